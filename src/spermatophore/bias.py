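"""Sex- and tissue-bias classification of gene expression.

Two independent rule systems label every gene:

*Sex axis* (male vs female whole-body expression): a gene is
``male_biased`` when its male/female mean-FPKM fold exceeds the sex
threshold *and* the male libraries contributed at least a minimum
combined number of unique reads; a gene passing the fold test but
failing the read guard is called ``female_biased`` (the guard exists
because a large fold on negligible male evidence is not credible male
expression).  A fold below the reciprocal threshold is
``female_biased``; an undefined fold (zero female mean) is
``excluded``; the intermediate band is ``unbiased``.

*Tissue axis* (testes vs male accessory gland, MAG): genes whose
combined testes+MAG unique reads fall below a floor are
``low_expression``; otherwise a fold of at least the tissue threshold
toward one tissue with fewer than a ceiling of unique reads in the
other tissue is ``*_specific``; the same fold without the read
condition is ``*_biased``; anything else is ``unbiased``.  Genes on
the female-biased sex stratum are classified but reported apart.

Rule precedence (low_expression -> specific -> biased -> unbiased)
makes the five tissue categories mutually exclusive, so class counts
sum to their denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "ClassifierThresholds",
    "classify_sex",
    "classify_tissue",
    "classify_table",
    "class_partition_counts",
    "SEX_CLASSES",
    "TISSUE_CLASSES",
]

SEX_CLASSES = ("male_biased", "female_biased", "unbiased", "excluded")
TISSUE_CLASSES = (
    "testes_specific",
    "mag_specific",
    "testes_biased",
    "mag_biased",
    "unbiased",
    "low_expression",
    "not_evaluated",
)


@dataclass(frozen=True)
class ClassifierThresholds:
    """Thresholds of the bias rule system.

    ``sex_fold`` uses a strict comparison (> fold) and ``tissue_fold``
    an inclusive one (>= fold, "at least") by default; both are
    configurable because published rule statements differ in wording.
    ``specific_other_max_reads`` and ``low_expression_total`` are
    exclusive upper bounds (strictly fewer reads than the value).
    """

    sex_fold: float = 5.0
    male_min_unique_reads: int = 100
    tissue_fold: float = 5.0
    specific_other_max_reads: int = 50
    low_expression_total: int = 100
    sex_strict: bool = True
    tissue_strict: bool = False

    def __post_init__(self) -> None:
        if self.sex_fold <= 1 or self.tissue_fold <= 1:
            raise ValueError("fold thresholds must exceed 1")
        if min(self.male_min_unique_reads, self.specific_other_max_reads,
               self.low_expression_total) <= 0:
            raise ValueError("read thresholds must be positive")


def _passes(fold: float, threshold: float, strict: bool) -> bool:
    return fold > threshold if strict else fold >= threshold


def classify_sex(
    male_mean: float,
    female_mean: float,
    male_unique_reads: int,
    thresholds: ClassifierThresholds | None = None,
) -> Tuple[str, str]:
    """Sex-bias class of one gene; returns ``(class, rule_fired)``."""
    t = thresholds or ClassifierThresholds()
    if female_mean == 0:
        return "excluded", "undefined male/female fold (zero female mean)"
    fold = male_mean / female_mean
    if _passes(fold, t.sex_fold, t.sex_strict):
        if male_unique_reads >= t.male_min_unique_reads:
            return "male_biased", (
                f"fold {fold:.3g} over threshold with "
                f"{male_unique_reads} >= {t.male_min_unique_reads} male reads"
            )
        return "female_biased", (
            f"fold {fold:.3g} over threshold but only "
            f"{male_unique_reads} < {t.male_min_unique_reads} male reads"
        )
    if fold < 1.0 / t.sex_fold:
        return "female_biased", f"fold {fold:.3g} below reciprocal threshold"
    return "unbiased", f"fold {fold:.3g} inside unbiased band"


def classify_tissue(
    testes_mean: float,
    mag_mean: float,
    testes_unique_reads: int,
    mag_unique_reads: int,
    thresholds: ClassifierThresholds | None = None,
) -> Tuple[str, str]:
    """Tissue-bias class of one gene; returns ``(class, rule_fired)``.

    A zero mean in the disfavoured tissue counts as an arbitrarily
    large fold toward the other tissue (the read-count conditions still
    gate the specific/low-expression outcomes).
    """
    t = thresholds or ClassifierThresholds()
    combined = testes_unique_reads + mag_unique_reads
    if combined < t.low_expression_total:
        return "low_expression", (
            f"combined reads {combined} < {t.low_expression_total}"
        )
    for this_mean, other_mean, other_reads, label in (
        (testes_mean, mag_mean, mag_unique_reads, "testes"),
        (mag_mean, testes_mean, testes_unique_reads, "mag"),
    ):
        if other_mean == 0:
            fold = np.inf if this_mean > 0 else np.nan
        else:
            fold = this_mean / other_mean
        if np.isfinite(fold) and not _passes(fold, t.tissue_fold, t.tissue_strict):
            continue
        if np.isnan(fold):
            continue
        if other_reads < t.specific_other_max_reads:
            return f"{label}_specific", (
                f"{label} fold {fold:.3g} with {other_reads} "
                f"< {t.specific_other_max_reads} reads in the other tissue"
            )
        return f"{label}_biased", f"{label} fold {fold:.3g} over threshold"
    return "unbiased", "fold below tissue threshold in both directions"


def classify_table(
    mean_fpkm: pd.DataFrame,
    read_totals: pd.DataFrame,
    thresholds: ClassifierThresholds | None = None,
    male_group: str = "male",
    female_group: str = "female",
    testes_group: str = "testes",
    mag_group: str = "mag",
) -> pd.DataFrame:
    """Classify every gene on both axes.

    ``mean_fpkm`` / ``read_totals`` are gene x group tables from
    :func:`spermatophore.expression.pool_groups`.  Axes whose groups
    are absent are labelled ``not_evaluated``.  Returns one row per
    gene with classes, the supporting folds and read totals, the rules
    fired, and the reporting stratum (``female_biased`` genes are
    reported apart on the tissue axis).
    """
    t = thresholds or ClassifierThresholds()
    has_sex = male_group in mean_fpkm.columns and female_group in mean_fpkm.columns
    has_tissue = testes_group in mean_fpkm.columns and mag_group in mean_fpkm.columns
    rows = []
    for gene in mean_fpkm.index:
        rec: dict = {"gene_id": gene}
        if has_sex:
            m = float(mean_fpkm.at[gene, male_group])
            f = float(mean_fpkm.at[gene, female_group])
            mreads = int(read_totals.at[gene, male_group])
            sex_class, sex_rule = classify_sex(m, f, mreads, t)
            rec.update(
                male_mean_fpkm=m,
                female_mean_fpkm=f,
                male_unique_reads=mreads,
                male_female_fold=(m / f if f > 0 else np.nan),
                sex_class=sex_class,
                sex_rule=sex_rule,
            )
        else:
            rec.update(sex_class="not_evaluated", sex_rule="sex groups absent")
        if has_tissue:
            te = float(mean_fpkm.at[gene, testes_group])
            ma = float(mean_fpkm.at[gene, mag_group])
            tr = int(read_totals.at[gene, testes_group])
            mr = int(read_totals.at[gene, mag_group])
            tissue_class, tissue_rule = classify_tissue(te, ma, tr, mr, t)
            rec.update(
                testes_mean_fpkm=te,
                mag_mean_fpkm=ma,
                testes_unique_reads=tr,
                mag_unique_reads=mr,
                testes_mag_fold=(te / ma if ma > 0 else np.nan),
                tissue_class=tissue_class,
                tissue_rule=tissue_rule,
            )
        else:
            rec.update(tissue_class="not_evaluated", tissue_rule="tissue groups absent")
        rec["stratum"] = (
            "female_biased" if rec.get("sex_class") == "female_biased" else "main"
        )
        rows.append(rec)
    return pd.DataFrame(rows).set_index("gene_id")


def class_partition_counts(calls: pd.DataFrame) -> dict:
    """Per-class counts with the denominators used for percentages.

    Sex percentages are taken over genes not ``excluded``; tissue
    percentages over genes outside the female-biased stratum (whose
    tissue classes are tallied separately).
    """
    if calls.empty:
        raise ValueError("no classification calls")
    out: dict = {}
    if "sex_class" in calls and not (calls["sex_class"] == "not_evaluated").all():
        sex_counts = calls["sex_class"].value_counts().to_dict()
        excluded = sex_counts.pop("excluded", 0)
        out["sex"] = {
            "counts": sex_counts,
            "excluded": excluded,
            "denominator": int(len(calls) - excluded),
        }
    if "tissue_class" in calls and not (calls["tissue_class"] == "not_evaluated").all():
        main = calls.loc[calls["stratum"] == "main"]
        strat = calls.loc[calls["stratum"] == "female_biased"]
        out["tissue"] = {
            "counts": main["tissue_class"].value_counts().to_dict(),
            "denominator": int(len(main)),
            "female_stratum_counts": strat["tissue_class"].value_counts().to_dict(),
            "female_stratum_size": int(len(strat)),
        }
    return out
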