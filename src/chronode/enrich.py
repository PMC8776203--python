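"""Gene-set over-representation with direction calls.

Classic per-term one-sided Fisher (hypergeometric tail) over-representation
of a significant gene list against the tested-gene universe, with two
catalogue-specific rules: terms overlapping fewer than ``min_sig``
significant genes are excluded before BH correction, and each retained term
gets a direction call — *down* when down-regulated overlapping genes
outnumber up-regulated ones more than 2:1, *up* for the symmetric case,
otherwise *affected* (mixed-direction genes count in neither tally).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .detest import bh_adjust


@dataclass
class GeneSetCollection:
    """Named gene sets with descriptions (GMT-backed)."""

    sets: dict[str, set[str]]
    descriptions: dict[str, str]

    def __post_init__(self) -> None:
        empty = [n for n, s in self.sets.items() if not s]
        if empty:
            raise ValueError(f"empty gene set(s): {empty}")

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: per line, set name, description, tab-separated members.

    Member whitespace is trimmed and duplicates collapsed.  A line with
    fewer than three fields raises with its line number.
    """
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: malformed GMT line {lineno} (need >= 3 fields)")
            name = fields[0].strip()
            if name in sets:
                raise ValueError(f"{path}: duplicate set name {name!r} at line {lineno}")
            members = {g.strip() for g in fields[2:] if g.strip()}
            if not members:
                raise ValueError(f"{path}: set {name!r} at line {lineno} has no members")
            sets[name] = members
            descriptions[name] = fields[1].strip()
    if not sets:
        warnings.warn(f"{path}: empty GMT file", stacklevel=2)
        return GeneSetCollection(sets={}, descriptions={})
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name in collection.sets:
            members = "\t".join(sorted(collection.sets[name]))
            fh.write(f"{name}\t{collection.descriptions.get(name, '')}\t{members}\n")


def overrepresentation(
    significant: Iterable[str],
    universe: Iterable[str],
    collection: GeneSetCollection,
    min_sig: int = 5,
) -> pd.DataFrame:
    """One-sided Fisher over-representation of each set among the significant genes.

    The 2x2 table per term is membership x significance over the universe;
    p is the hypergeometric upper tail at the observed overlap.  Terms with
    overlap below ``min_sig`` are dropped before BH correction.
    """
    sig = set(significant)
    uni = set(universe)
    if not sig <= uni:
        missing = sorted(sig - uni)[:5]
        raise ValueError(f"significant genes missing from the universe, e.g. {missing}")
    n_uni, n_sig = len(uni), len(sig)
    rows = []
    for name, members in collection.sets.items():
        in_uni = members & uni
        overlap = in_uni & sig
        if len(overlap) < min_sig:
            continue
        p = float(hypergeom.sf(len(overlap) - 1, n_uni, len(in_uni), n_sig))
        rows.append(
            {
                "term": name,
                "description": collection.descriptions.get(name, ""),
                "set_size": len(in_uni),
                "overlap": len(overlap),
                "p": p,
                "overlap_genes": ",".join(sorted(overlap)),
            }
        )
    out = pd.DataFrame(
        rows, columns=["term", "description", "set_size", "overlap", "p", "overlap_genes"]
    )
    out["fdr"] = bh_adjust(out["p"].to_numpy()) if len(out) else np.nan
    return out


def term_direction(direction_labels: Iterable[str]) -> tuple[str, float]:
    """Direction call for a term from its overlapping genes' direction labels.

    Returns (call, down:up ratio).  down when down/up > 2, up when up/down > 2
    (the symmetric rule), otherwise affected; mixed genes are counted in
    neither tally and an empty denominator with a non-zero numerator is
    treated as an infinite ratio.
    """
    labels = list(direction_labels)
    n_down = sum(1 for x in labels if x == "down")
    n_up = sum(1 for x in labels if x == "up")
    ratio = np.inf if (n_up == 0 and n_down > 0) else (n_down / n_up if n_up else np.nan)
    if n_down > 2 * n_up and n_down > 0:
        return "down", ratio
    if n_up > 2 * n_down and n_up > 0:
        return "up", ratio
    return "affected", ratio


def enrich_with_direction(
    classification: pd.DataFrame,
    universe: Iterable[str],
    collection: GeneSetCollection,
    min_sig: int = 5,
) -> pd.DataFrame:
    """Over-representation of the classified targets, annotated with direction calls."""
    table = overrepresentation(classification.index, universe, collection, min_sig=min_sig)
    calls, ratios = [], []
    for genes in table["overlap_genes"]:
        labels = classification.loc[genes.split(","), "direction"]
        call, ratio = term_direction(labels)
        calls.append(call)
        ratios.append(ratio)
    table["direction"] = calls
    table["down_up_ratio"] = ratios
    return table
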