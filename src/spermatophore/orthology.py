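"""Reciprocal-best-hit orthology and semen-protein cross-referencing.

Pairwise proteome comparisons arrive as standard 12-column tabular
alignment hit files (qseqid sseqid pident length mismatch gapopen
qstart qend sstart send evalue bitscore).  Hits at or above the
e-value threshold are discarded *before* best-hit selection, so a
strong-but-filtered hit never shadows a surviving weaker one.  Two
proteins are called orthologs when each is the other's best surviving
hit; ties are broken deterministically by e-value, then bit score,
then lexicographic subject id.

Called orthologs are classified against curated seminal-fluid-protein
(SFP) and sperm-protein id lists of the partner species, and
multi-species ortholog sets are summarised as Venn region counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Dict, Iterable, List, Mapping, Sequence, Set, Tuple

import pandas as pd

__all__ = [
    "BLAST_COLUMNS",
    "OrthologyParams",
    "read_hit_table",
    "best_hits",
    "rbh",
    "semen_crossref",
    "intersect_sets",
]

BLAST_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]
_NUMERIC = {
    "pident": float, "length": int, "mismatch": int, "gapopen": int,
    "qstart": int, "qend": int, "sstart": int, "send": int,
    "evalue": float, "bitscore": float,
}


@dataclass(frozen=True)
class OrthologyParams:
    """Orthology-calling parameters; the e-value cut is exclusive."""

    e_threshold: float = 1e-10

    def __post_init__(self) -> None:
        if not self.e_threshold > 0:
            raise ValueError("e_threshold must be positive")


class HitTableParseError(ValueError):
    """Malformed row in a tabular hit file; carries the line number."""


def read_hit_table(path) -> pd.DataFrame:
    """Parse a 12-column tabular hit file ('#' comment lines tolerated)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise HitTableParseError(
                    f"{path}: line {lineno}: expected 12 columns, got {len(fields)}"
                )
            rec = {}
            for name, raw in zip(BLAST_COLUMNS, fields):
                conv = _NUMERIC.get(name)
                if conv is None:
                    rec[name] = raw
                    continue
                try:
                    rec[name] = conv(raw)
                except ValueError as exc:
                    raise HitTableParseError(
                        f"{path}: line {lineno}: bad value {raw!r} for {name}"
                    ) from exc
            rows.append(rec)
    return pd.DataFrame(rows, columns=BLAST_COLUMNS)


def best_hits(
    hits: pd.DataFrame, params: OrthologyParams | None = None
) -> Dict[str, str]:
    """Map each query to its best surviving subject.

    Rows with e-value >= threshold are dropped first; multiple rows for
    one query-subject pair (separate HSPs) collapse to the pair's
    lowest e-value (highest bit score on ties); the best subject per
    query minimises e-value, then maximises bit score, then takes the
    lexicographically smallest subject id.  Self-hits are ignored.
    """
    params = params or OrthologyParams()
    if hits.empty:
        return {}
    surviving = hits.loc[
        (hits["evalue"] < params.e_threshold) & (hits["qseqid"] != hits["sseqid"])
    ]
    if surviving.empty:
        return {}
    ordered = surviving.sort_values(
        ["qseqid", "evalue", "bitscore", "sseqid"],
        ascending=[True, True, False, True],
        kind="mergesort",
    )
    per_pair = ordered.drop_duplicates(["qseqid", "sseqid"], keep="first")
    best = per_pair.drop_duplicates("qseqid", keep="first")
    return dict(zip(best["qseqid"], best["sseqid"]))


def rbh(
    forward: pd.DataFrame,
    reverse: pd.DataFrame,
    params: OrthologyParams | None = None,
) -> List[Tuple[str, str]]:
    """Reciprocal-best-hit ortholog pairs.

    ``(a, b)`` is returned iff the best forward hit of ``a`` is ``b``
    and the best reverse hit of ``b`` is ``a``.  The result is a
    one-to-one matching, sorted by query id.
    """
    params = params or OrthologyParams()
    fwd = best_hits(forward, params)
    rev = best_hits(reverse, params)
    return sorted((a, b) for a, b in fwd.items() if rev.get(b) == a)


SEMEN_CLASSES = ("SFP", "sperm", "both", "neither", "no_ortholog")


def semen_crossref(
    pairs: Iterable[Tuple[str, str]],
    sfp_list: Iterable[str],
    sperm_list: Iterable[str],
    all_query_ids: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Classify ortholog pairs against published SFP and sperm id lists.

    Returns one row per query protein: ``protein_id, ortholog_id,
    semen_class``.  Queries in ``all_query_ids`` without an ortholog
    are reported as ``no_ortholog``.
    """
    sfp = set(sfp_list)
    sperm = set(sperm_list)
    pair_map = dict(pairs)
    universe = list(all_query_ids) if all_query_ids is not None else list(pair_map)
    rows = []
    for pid in universe:
        ortho = pair_map.get(pid)
        if ortho is None:
            cls = "no_ortholog"
        elif ortho in sfp and ortho in sperm:
            cls = "both"
        elif ortho in sfp:
            cls = "SFP"
        elif ortho in sperm:
            cls = "sperm"
        else:
            cls = "neither"
        rows.append({"protein_id": pid, "ortholog_id": ortho, "semen_class": cls})
    return pd.DataFrame(rows, columns=["protein_id", "ortholog_id", "semen_class"])


def intersect_sets(named_sets: Mapping[str, Set[str]]) -> Dict[str, int]:
    """Venn region counts over up to six named sets.

    Each id in the union belongs to exactly one membership pattern; the
    returned dict maps ``"A&B"``-style keys (member names joined in
    input order) to the count of ids showing exactly that pattern.
    Patterns with zero count are included, so values sum to the size of
    the union over all 2^k - 1 regions.
    """
    names = list(named_sets)
    k = len(names)
    if not 1 <= k <= 6:
        raise ValueError(
            f"{k} sets unsupported for a Venn summary (1..6); "
            "use a pairwise membership matrix instead"
        )
    regions: Dict[str, int] = {}
    for r in range(1, k + 1):
        for combo in combinations(names, r):
            regions["&".join(combo)] = 0
    union = set().union(*named_sets.values())
    for item in union:
        pattern = tuple(n for n in names if item in named_sets[n])
        regions["&".join(pattern)] += 1
    return regions
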