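"""Cross-contrast set logic, genomic-category tallies and over-representation.

Probes significant in several contrasts are combined through an
inclusion-exclusion (Venn) partition; a "consistent subtype-specific set"
is the set of probes called in the same direction in every one of a list of
target contrasts (e.g. hypomethylated in TNBC against all luminal, luminal
A and luminal B tumors).  Genomic-category distributions tally the five
locus classes (exonic, intronic, sense-overlapping, antisense, intergenic)
of significant probes per contrast and direction.

Host-gene enrichment is the standard hypergeometric over-representation
test on user-supplied gene sets (GMT format) against a configurable
universe (by default the deduplicated host genes of all retained probes),
with Benjamini-Hochberg adjustment across terms.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .differential import bh_adjust
from .io import CATEGORIES, ProbeAnnotation, annotation_frame

DIRECTIONS = ("hyper", "hypo")


class SetsError(ValueError):
    pass


def membership_table(contrasts: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Probe x contrast table of calls; probes not tested in a contrast get
    ``untested``."""
    all_probes = sorted(set().union(*[set(c["probe_id"]) for c in contrasts.values()]))
    table = pd.DataFrame("untested", index=pd.Index(all_probes, name="probe_id"),
                         columns=list(contrasts))
    for name, frame in contrasts.items():
        table.loc[frame["probe_id"].values, name] = frame["call"].values
    return table


def venn_counts(
    memberships: pd.DataFrame, contrasts: Sequence[str], direction: str
) -> dict[frozenset, int]:
    """Counts for every region of the inclusion-exclusion partition.

    Keys are frozensets of contrast names (the region "in exactly these
    contrasts"); regions sum to the size of the union of significant sets.
    """
    if direction not in DIRECTIONS:
        raise SetsError(f"direction must be one of {DIRECTIONS}")
    if not 2 <= len(contrasts) <= 4:
        raise SetsError("venn partition supports 2-4 contrasts")
    unknown = [c for c in contrasts if c not in memberships.columns]
    if unknown:
        raise SetsError(f"unknown contrasts: {unknown}")
    in_set = {c: memberships[c] == direction for c in contrasts}
    counts: dict[frozenset, int] = {}
    n = len(contrasts)
    for mask in range(1, 2 ** n):
        included = [c for i, c in enumerate(contrasts) if mask >> i & 1]
        excluded = [c for c in contrasts if c not in included]
        sel = np.ones(len(memberships), dtype=bool)
        for c in included:
            sel &= in_set[c].values
        for c in excluded:
            sel &= ~in_set[c].values
        counts[frozenset(included)] = int(sel.sum())
    return counts


def venn_table(counts: dict[frozenset, int], direction: str) -> pd.DataFrame:
    """Flatten a region->count map into the ``sets`` schema (region key is
    the '&'-joined sorted contrast names)."""
    rows = [
        {"region": "&".join(sorted(region)), "direction": direction, "count": c}
        for region, c in sorted(counts.items(), key=lambda kv: (len(kv[0]), sorted(kv[0])))
    ]
    return pd.DataFrame(rows)


def consistent_specific_set(
    memberships: pd.DataFrame, contrasts: Sequence[str], direction: str
) -> list[str]:
    """Probes called ``direction`` in *every* target contrast."""
    if direction not in DIRECTIONS:
        raise SetsError(f"direction must be one of {DIRECTIONS}")
    if len(contrasts) < 2:
        raise SetsError("need >= 2 target contrasts")
    if memberships.empty:
        return []
    mask = np.ones(len(memberships), dtype=bool)
    for c in contrasts:
        if c not in memberships.columns:
            raise SetsError(f"unknown contrast {c!r}")
        mask &= (memberships[c] == direction).values
    return memberships.index[mask].tolist()


def category_distribution(
    memberships: pd.DataFrame,
    annotation: Sequence[ProbeAnnotation] | pd.DataFrame,
) -> pd.DataFrame:
    """Genomic-category counts of significant probes per contrast and direction.

    Rows are (contrast, direction); columns the five categories.  Row sums
    equal the significant counts, so an all-ns table is all-zero.
    """
    ann = annotation if isinstance(annotation, pd.DataFrame) else annotation_frame(annotation)
    missing = [p for p in memberships.index if p not in ann.index]
    if missing:
        raise SetsError(f"unannotated probes: {missing[:5]}")
    rows = []
    for contrast in memberships.columns:
        for direction in DIRECTIONS:
            probes = memberships.index[memberships[contrast] == direction]
            cats = ann.loc[probes, "category"]
            counts = {c: int((cats == c).sum()) for c in CATEGORIES}
            rows.append({"contrast": contrast, "direction": direction, **counts})
    return pd.DataFrame(rows).set_index(["contrast", "direction"])


def host_gene_query(
    probes: Iterable[str],
    annotation: Sequence[ProbeAnnotation] | pd.DataFrame,
) -> list[str]:
    """Each probe contributes its host gene once (deduplicated, sorted)."""
    ann = annotation if isinstance(annotation, pd.DataFrame) else annotation_frame(annotation)
    return sorted({ann.loc[p, "host_gene"] for p in probes})


def read_gmt(path: str | Path) -> dict[str, tuple[str, set[str]]]:
    """GMT gene sets: term_id -> (description, member genes)."""
    sets: dict[str, tuple[str, set[str]]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = (parts[1], {g for g in parts[2:] if g})
    return sets


def hypergeometric_ora(
    query: Iterable[str],
    gene_sets: Mapping[str, tuple[str, set[str]]],
    universe: Iterable[str],
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of each term in the query.

    p = P(X >= k) with X ~ Hypergeom(N=|universe|, K=|term ∩ universe|,
    n=|query|); k = 0 gives p = 1.  BH-adjusted q across terms; records
    with q < p_threshold are flagged significant.
    """
    universe = set(universe)
    if not universe:
        raise SetsError("empty universe")
    query = set(query) & universe
    rows = []
    for term_id, (name, members) in gene_sets.items():
        members = members & universe
        K, n, N = len(members), len(query), len(universe)
        k = len(members & query)
        p = float(hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append({"term_id": term_id, "term_name": name,
                     "k": k, "K": K, "n": n, "N": N, "p": p})
    result = pd.DataFrame(rows)
    if result.empty:
        result["q"] = []
        result["significant"] = []
        return result
    result["q"] = bh_adjust(result["p"].values)
    result["significant"] = result["q"] < p_threshold
    return result.sort_values(["p", "term_id"]).reset_index(drop=True)
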