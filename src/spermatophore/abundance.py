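"""Protein-inventory filtering and emPAI abundance profiling.

Identification evidence (one row per protein: id, MOWSE-based score,
number of distinct observed peptides) is filtered at a score threshold,
then each retained protein is quantified with the exponentially
modified protein abundance index:

    PAI    = N_observed / N_observable
    emPAI  = 10 ** PAI - 1
    %emPAI = 100 * emPAI / sum(emPAI)

``N_observable`` comes from an in-silico tryptic digest of the protein
sequence (see :mod:`spermatophore.digest`).  Per-GO-class emPAI sums
give a functional abundance profile, with novel (similarity-free)
proteins always kept as their own class.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Mapping, Sequence, Set

import numpy as np
import pandas as pd

from .digest import DigestParams, digest_trypsin, count_observable

__all__ = [
    "filter_identifications",
    "compute_abundance",
    "functional_profile",
    "top_k_share",
    "NOVEL_CLASS",
    "UNKNOWN_CONSERVED_CLASS",
]

log = logging.getLogger(__name__)

NOVEL_CLASS = "novel"
UNKNOWN_CONSERVED_CLASS = "unknown conserved"

EVIDENCE_COLUMNS = ["protein_id", "score", "n_observed"]


def filter_identifications(evidence: pd.DataFrame, score_threshold: float = 54.0) -> pd.DataFrame:
    """Retain identifications with ``score > score_threshold``.

    The threshold is exclusive: a score exactly at the threshold is
    dropped (it corresponds to a random-match probability of 5%, the
    boundary of significance).
    """
    if evidence.empty:
        return evidence.copy()
    kept = evidence.loc[evidence["score"] > score_threshold].reset_index(drop=True)
    log.info(
        "identification filter: retained %d of %d proteins at score > %g",
        len(kept), len(evidence), score_threshold,
    )
    return kept


def compute_abundance(
    evidence: pd.DataFrame,
    proteome: Mapping[str, str],
    params: DigestParams | None = None,
    go_map: Mapping[str, Set[str]] | None = None,
    novel_ids: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Compute PAI/emPAI/relative-emPAI for every protein in ``evidence``.

    Parameters
    ----------
    evidence:
        Table with columns ``protein_id``, ``score``, ``n_observed``.
    proteome:
        Mapping id -> amino-acid sequence; must cover every evidence id.
    params:
        Digest parameters defining observable peptides.
    go_map:
        Optional mapping id -> set of Molecular Function (Level III)
        class labels.
    novel_ids:
        Ids of proteins without similarity to known sequences.

    Returns
    -------
    DataFrame with columns ``protein_id, n_observed, n_observable, pai,
    empai, relative_empai, quantifiable, novel, go_classes``.  Proteins
    whose digest yields no observable peptide are flagged
    ``quantifiable=False``, carry NaN abundances and are excluded from
    the relative-emPAI normalisation.
    """
    if params is None:
        params = DigestParams()
    novel = set(novel_ids) if novel_ids is not None else set()
    go_map = go_map or {}

    missing = [pid for pid in evidence["protein_id"] if pid not in proteome]
    if missing:
        raise KeyError(f"evidence ids absent from proteome: {missing[:5]}")

    rows = []
    for pid, n_obs in zip(evidence["protein_id"], evidence["n_observed"]):
        n_observable = count_observable(digest_trypsin(proteome[pid], params), params)
        quantifiable = n_observable >= 1
        if quantifiable:
            pai = float(n_obs) / n_observable
            empai = 10.0 ** pai - 1.0
        else:
            pai = math.nan
            empai = math.nan
        rows.append(
            {
                "protein_id": pid,
                "n_observed": int(n_obs),
                "n_observable": int(n_observable),
                "pai": pai,
                "empai": empai,
                "quantifiable": quantifiable,
                "novel": pid in novel,
                "go_classes": ";".join(sorted(go_map.get(pid, set()))),
            }
        )
    out = pd.DataFrame(rows)
    n_bad = int((~out["quantifiable"]).sum()) if len(out) else 0
    if n_bad:
        log.warning("%d proteins had no observable peptide and are unquantifiable", n_bad)
    total = out.loc[out["quantifiable"], "empai"].sum()
    if len(out):
        out["relative_empai"] = np.where(
            out["quantifiable"] & (total > 0), 100.0 * out["empai"] / total, np.nan
        )
    else:
        out["relative_empai"] = pd.Series(dtype=float)
    return out


def _classes_of(row: pd.Series) -> Set[str]:
    if row["novel"]:
        return {NOVEL_CLASS}
    labels = {c for c in str(row.get("go_classes", "") or "").split(";") if c}
    return labels or {UNKNOWN_CONSERVED_CLASS}


def functional_profile(abundances: pd.DataFrame) -> pd.Series:
    """Per-class emPAI sums, sorted descending.

    Novel proteins form their own class and are never absorbed into a
    GO class; annotated proteins without a GO label fall into
    ``unknown conserved``.  Multi-class proteins contribute their full
    emPAI to each of their classes, so the profile is descriptive, not
    a partition of total emPAI.
    """
    sums: dict[str, float] = {}
    for _, row in abundances.iterrows():
        if not row.get("quantifiable", True):
            continue
        for label in _classes_of(row):
            sums[label] = sums.get(label, 0.0) + float(row["empai"])
    profile = pd.Series(sums, dtype=float)
    return profile.sort_values(ascending=False)


def top_k_share(abundances: pd.DataFrame, k: int) -> float:
    """Percent of total emPAI held by the ``k`` most abundant proteins.

    Ranking is by emPAI descending, ties broken lexicographically by
    protein id.  Only quantifiable proteins participate.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    quant = abundances.loc[abundances["quantifiable"]] if "quantifiable" in abundances else abundances
    if k > len(quant):
        raise ValueError(f"k={k} exceeds the {len(quant)} quantifiable proteins")
    ranked = quant.sort_values(["empai", "protein_id"], ascending=[False, True])
    total = quant["empai"].sum()
    if total <= 0:
        return 0.0
    return float(100.0 * ranked["empai"].head(k).sum() / total)
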