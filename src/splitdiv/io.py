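"""Readers and writers for the interchange formats.

Newick tree lists, NEXUS SPLITS blocks (SplitsTree dialect), presence /
boundary / cost CSV tables, food-web TSV edge lists, and a JSON result file.
Readers reject malformed input rather than silently coercing it; taxon-name
matching across files is exact and case-sensitive.
"""
from __future__ import annotations

import json
import logging
import re
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .foodweb import DietMatrix, FoodWeb
from .reserve import Landscape
from .splits import SplitSystem, TaxonSet, Tree, _parse_newick

logger = logging.getLogger(__name__)

__all__ = [
    "read_trees",
    "read_splits_nexus",
    "write_splits_nexus",
    "read_presence_csv",
    "read_boundary_csv",
    "read_costs_csv",
    "read_landscape",
    "read_foodweb_tsv",
    "write_result",
]


def read_trees(path: str | Path) -> list[Tree]:
    """Read one or more semicolon-terminated Newick trees from a file.

    All trees are placed on a shared TaxonSet (the sorted union of their leaf
    labels); quoted labels are preserved verbatim.
    """
    text = Path(path).read_text()
    if not text.strip():
        raise ValueError(f"{path}: empty tree file")
    try:
        dtrees = _parse_newick(text)
    except Exception as exc:
        raise ValueError(f"{path}: malformed Newick: {exc}") from exc
    if not dtrees:
        raise ValueError(f"{path}: no trees found")
    labels: set[str] = set()
    for t in dtrees:
        labels.update(lf.taxon.label for lf in t.leaf_node_iter())
    taxa = TaxonSet(sorted(labels))
    trees = [Tree(t, taxa) for t in dtrees]
    logger.info("read %d trees over %d taxa from %s", len(trees), taxa.n, path)
    return trees


# ---------------------------------------------------------------------------
# NEXUS SPLITS (SplitsTree dialect)

_BLOCK_RE = re.compile(
    r"BEGIN\s+(\w+)\s*;(.*?)END\s*;", re.IGNORECASE | re.DOTALL
)
_COMMENT_RE = re.compile(r"\[[^\]]*\]")


def _nexus_blocks(text: str) -> dict[str, str]:
    if not text.lstrip().upper().startswith("#NEXUS"):
        raise ValueError("not a NEXUS file (missing #NEXUS header)")
    return {m.group(1).upper(): m.group(2) for m in _BLOCK_RE.finditer(text)}


def _parse_taxlabels(block: str) -> list[str]:
    m = re.search(r"TAXLABELS(.*?);", block, re.IGNORECASE | re.DOTALL)
    if not m:
        raise ValueError("TAXA block lacks a TAXLABELS command")
    raw = m.group(1)
    labels = re.findall(r"'([^']*)'|\"([^\"]*)\"|(\S+)", raw)
    return [a or b or c for a, b, c in labels]


def read_splits_nexus(path: str | Path) -> SplitSystem:
    """Read a split system from a NEXUS file with TAXA and SPLITS blocks.

    Each MATRIX line of the SPLITS block carries a weight followed by the
    1-based indices of the taxa on one side of the split.  A CYCLE command
    (the circular ordering SplitsTree uses for drawing) is ignored with a
    warning.  Duplicate split lines merge by weight summation.
    """
    text = _COMMENT_RE.sub(" ", Path(path).read_text())
    blocks = _nexus_blocks(text)
    if "TAXA" not in blocks:
        raise ValueError(f"{path}: missing TAXA block")
    if "SPLITS" not in blocks:
        raise ValueError(f"{path}: missing SPLITS block")
    taxa = TaxonSet(_parse_taxlabels(blocks["TAXA"]))
    splits_block = blocks["SPLITS"]
    if re.search(r"\bCYCLE\b", splits_block, re.IGNORECASE):
        logger.warning("%s: CYCLE command in SPLITS block ignored", path)
        splits_block = re.sub(
            r"CYCLE[^;]*;", " ", splits_block, flags=re.IGNORECASE
        )
    m = re.search(r"MATRIX(.*?);", splits_block, re.IGNORECASE | re.DOTALL)
    if not m:
        raise ValueError(f"{path}: SPLITS block lacks a MATRIX command")
    system = SplitSystem(taxa)
    n_dupes = 0
    seen: set[tuple[int, ...]] = set()
    for lineno, line in enumerate(m.group(1).split(","), start=1):
        line = line.strip()
        if not line:
            continue
        fields = line.split()
        try:
            weight = float(fields[0])
            side = [int(x) for x in fields[1:]]
        except (ValueError, IndexError) as exc:
            raise ValueError(
                f"{path}: malformed split line {lineno}: {line!r}"
            ) from exc
        if not side:
            raise ValueError(f"{path}: split line {lineno} lists no taxa")
        bad = [i for i in side if i < 1 or i > taxa.n]
        if bad:
            raise ValueError(
                f"{path}: split line {lineno}: taxon indices {bad} out of "
                f"range 1..{taxa.n}"
            )
        memb = [0] * taxa.n
        for i in side:
            memb[i - 1] = 1
        key = tuple(memb) if memb[0] == 0 else tuple(1 - v for v in memb)
        if key in seen:
            n_dupes += 1
        seen.add(key)
        system.add(memb, weight)
    if n_dupes:
        logger.warning(
            "%s: %d duplicate split lines merged by weight summation",
            path, n_dupes,
        )
    return system


def write_splits_nexus(system: SplitSystem, path: str | Path) -> None:
    """Write a split system as a SplitsTree-compatible NEXUS file."""
    taxa = system.taxa
    lines = ["#NEXUS", "", "BEGIN TAXA;", f"DIMENSIONS NTAX={taxa.n};",
             "TAXLABELS"]
    lines.extend(f"  '{lab}'" for lab in taxa.labels)
    lines.append(";")
    lines.append("END;")
    lines.append("")
    lines.append("BEGIN SPLITS;")
    lines.append(f"DIMENSIONS NTAX={taxa.n} NSPLITS={len(system)};")
    lines.append("FORMAT LABELS=NO WEIGHTS=YES;")
    lines.append("MATRIX")
    for idx, (sp, w) in enumerate(system, start=1):
        side = [str(i + 1) for i in range(taxa.n) if sp.mask1 >> i & 1]
        lines.append(f"  [{idx}] {w:.12g} {' '.join(side)},")
    lines.append(";")
    lines.append("END;")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Landscape CSV tables


def read_presence_csv(path: str | Path) -> tuple[list[str], TaxonSet, np.ndarray]:
    """Presence table: header row = taxon labels, first column = area ids,
    cells strictly 0/1.  Returns (area ids, taxa, m x n matrix)."""
    df = pd.read_csv(path, index_col=0)
    if df.empty:
        raise ValueError(f"{path}: empty presence table")
    values = df.to_numpy()
    if not np.isin(values, (0, 1)).all():
        raise ValueError(f"{path}: presence cells must be 0 or 1")
    areas = [str(a) for a in df.index]
    taxa = TaxonSet(str(c) for c in df.columns)
    return areas, taxa, values.astype(np.int8)


def read_boundary_csv(path: str | Path, areas: list[str]) -> np.ndarray:
    """Square boundary-length matrix with area-id header row and column."""
    df = pd.read_csv(path, index_col=0)
    rows = [str(a) for a in df.index]
    cols = [str(c) for c in df.columns]
    if rows != cols:
        raise ValueError(f"{path}: boundary row and column ids differ")
    missing = [a for a in areas if a not in rows]
    if missing:
        raise ValueError(f"{path}: boundary matrix lacks areas {missing}")
    df = df.loc[areas, areas]
    return df.to_numpy(dtype=float)


def read_costs_csv(
    path: str | Path, areas: list[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Cost table with columns area, cost and optional urban (0/1)."""
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    if "area" not in cols or "cost" not in cols:
        raise ValueError(f"{path}: cost table needs 'area' and 'cost' columns")
    df = df.set_index(df[cols["area"]].astype(str))
    missing = [a for a in areas if a not in df.index]
    if missing:
        raise ValueError(f"{path}: cost table lacks areas {missing}")
    df = df.loc[areas]
    costs = df[cols["cost"]].to_numpy(dtype=float)
    if "urban" in cols:
        urban = df[cols["urban"]].to_numpy().astype(bool)
    else:
        urban = np.zeros(len(areas), dtype=bool)
    return costs, urban


def read_landscape(
    presence_path: str | Path,
    boundary_path: str | Path | None,
    costs_path: str | Path | None,
    beta: float = 0.0,
) -> tuple[Landscape, TaxonSet]:
    areas, taxa, presence = read_presence_csv(presence_path)
    m = len(areas)
    if boundary_path is not None:
        boundary = read_boundary_csv(boundary_path, areas)
    else:
        boundary = np.zeros((m, m))
    if costs_path is not None:
        costs, urban = read_costs_csv(costs_path, areas)
    else:
        costs, urban = np.ones(m), np.zeros(m, dtype=bool)
    return Landscape(areas, presence, costs, boundary, beta, urban), taxa


def write_presence_csv(landscape: Landscape, taxa: TaxonSet,
                       path: str | Path) -> None:
    pd.DataFrame(
        landscape.presence, index=landscape.areas, columns=list(taxa.labels)
    ).to_csv(path)


def write_boundary_csv(landscape: Landscape, path: str | Path) -> None:
    pd.DataFrame(
        landscape.boundary, index=landscape.areas, columns=landscape.areas
    ).to_csv(path)


def write_costs_csv(landscape: Landscape, path: str | Path) -> None:
    pd.DataFrame(
        {
            "area": landscape.areas,
            "cost": landscape.costs,
            "urban": landscape.urban.astype(int),
        }
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Food-web TSV


def read_foodweb_tsv(
    path: str | Path, taxa: TaxonSet | None = None
) -> tuple[FoodWeb, DietMatrix | None]:
    """Food-web edge list: predator <TAB> prey <TAB> optional proportion.

    A header line is required.  If no line carries a proportion the web is
    unweighted and the diet matrix is None; a mixture of weighted and
    unweighted lines is rejected.
    """
    df = pd.read_csv(path, sep="\t")
    cols = [c.lower() for c in df.columns]
    if len(cols) < 2 or cols[0] != "predator" or cols[1] != "prey":
        raise ValueError(
            f"{path}: expected header 'predator<TAB>prey[<TAB>proportion]'"
        )
    has_prop = len(cols) >= 3
    preds = df.iloc[:, 0].astype(str)
    preys = df.iloc[:, 1].astype(str)
    if taxa is None:
        taxa = TaxonSet(sorted(set(preds) | set(preys)))
    arrows = list(zip(preds, preys))
    web = FoodWeb(taxa, arrows)
    diets = None
    if has_prop:
        props = df.iloc[:, 2]
        if props.isna().any():
            raise ValueError(f"{path}: missing proportions on some lines")
        rows: dict[int, dict[int, float]] = {}
        for pred, prey, w in zip(preds, preys, props.astype(float)):
            rows.setdefault(taxa.index(pred), {})[taxa.index(prey)] = w
        diets = DietMatrix(web, rows)
    return web, diets


def write_foodweb_tsv(
    web: FoodWeb, diets: DietMatrix | None, path: str | Path
) -> None:
    lines = ["predator\tprey" + ("\tproportion" if diets else "")]
    for j, i in web.arrows():
        row = f"{web.taxa.labels[j]}\t{web.taxa.labels[i]}"
        if diets:
            row += f"\t{diets.weight(j, i):.12g}"
        lines.append(row)
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Result files


def write_result(payload: dict[str, Any], path: str | Path) -> None:
    """Write a machine-readable result file (JSON, keys sorted)."""

    def default(o):
        if isinstance(o, (frozenset, set)):
            return sorted(o)
        if isinstance(o, np.integer):
            return int(o)
        if isinstance(o, np.floating):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"cannot serialize {type(o)}")

    Path(path).write_text(
        json.dumps(payload, indent=2, sort_keys=True, default=default) + "\n"
    )
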