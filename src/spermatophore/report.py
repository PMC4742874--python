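"""Summary-report assembly: class counts, percentages and profiles.

Percentages are integer, rounded half away from zero, and always
carry their count and denominator so the report is self-auditing:
``percent(count, denominator)`` can be recomputed from the report's
own numbers.  Denominator conventions: novelty and orthology
percentages are taken over the full inventory; sex percentages over
genes not excluded from the fold calculation; tissue percentages over
genes outside the female-biased stratum.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional

import pandas as pd

__all__ = ["percent", "build_report", "SummaryReport"]


def percent(count: int, denominator: int) -> int:
    """Integer percentage, rounded half away from zero."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if not 0 <= count <= denominator:
        raise ValueError("count must lie in [0, denominator]")
    return int(math.floor(100.0 * count / denominator + 0.5))


def _with_percent(counts: Mapping[str, int], denominator: int) -> Dict[str, dict]:
    return {
        label: {"n": int(n), "percent": percent(int(n), denominator)}
        for label, n in sorted(counts.items())
    }


@dataclass
class SummaryReport:
    """Assembled pipeline summary; serialisable as JSON and text."""

    inventory_size: int
    novelty: Optional[dict] = None
    sex: Optional[dict] = None
    tissue: Optional[dict] = None
    orthology: Optional[dict] = None
    functional_profile: Optional[Dict[str, float]] = None
    top_k_share: Optional[dict] = None
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "inventory_size": self.inventory_size,
            "novelty": self.novelty,
            "sex": self.sex,
            "tissue": self.tissue,
            "orthology": self.orthology,
            "functional_profile": self.functional_profile,
            "top_k_share": self.top_k_share,
            "provenance": self.provenance,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    def to_text(self) -> str:
        lines = [f"Inventory: {self.inventory_size} proteins"]
        if self.novelty:
            lines.append("Novelty (over full inventory):")
            for label, v in self.novelty["classes"].items():
                lines.append(f"  {label}: n={v['n']} ({v['percent']}%)")
        if self.sex:
            lines.append(
                f"Sex bias (denominator {self.sex['denominator']}, "
                f"{self.sex['excluded']} excluded):"
            )
            for label, v in self.sex["classes"].items():
                lines.append(f"  {label}: n={v['n']} ({v['percent']}%)")
        if self.tissue:
            lines.append(f"Tissue bias (denominator {self.tissue['denominator']}):")
            for label, v in self.tissue["classes"].items():
                lines.append(f"  {label}: n={v['n']} ({v['percent']}%)")
            strat = self.tissue.get("female_stratum", {})
            if strat:
                lines.append(
                    "  female-biased stratum (reported apart): "
                    + ", ".join(f"{k}={v}" for k, v in sorted(strat.items()))
                )
        if self.orthology:
            lines.append("Orthology (over full inventory):")
            for sp, v in sorted(self.orthology.items()):
                lines.append(
                    f"  {sp}: {v['n_orthologs']} orthologs "
                    f"({v['percent_orthologs']}%), semen classes "
                    + ", ".join(f"{k}={n}" for k, n in sorted(v["semen_classes"].items()))
                )
        if self.functional_profile:
            lines.append("Functional profile (class: summed emPAI):")
            for label, v in self.functional_profile.items():
                lines.append(f"  {label}: {v:.2f}")
        if self.top_k_share:
            lines.append(
                f"Top-{self.top_k_share['k']} proteins hold "
                f"{self.top_k_share['share_percent']:.1f}% of total emPAI"
            )
        return "\n".join(lines) + "\n"


def build_report(
    inventory_size: int,
    partition: Optional[dict] = None,
    orthology_calls: Optional[Mapping[str, pd.DataFrame]] = None,
    profile: Optional[pd.Series] = None,
    abundances: Optional[pd.DataFrame] = None,
    n_novel: Optional[int] = None,
    top_k: int = 6,
    provenance: Optional[dict] = None,
) -> SummaryReport:
    """Assemble the cross-stage summary.

    ``partition`` is the output of
    :func:`spermatophore.bias.class_partition_counts`;
    ``orthology_calls`` maps species to the per-protein call table.
    Missing stages are simply absent from the report (graceful
    degradation), never fabricated.
    """
    from .abundance import top_k_share  # local import avoids a cycle

    report = SummaryReport(inventory_size=int(inventory_size), provenance=provenance or {})
    if n_novel is not None:
        report.novelty = {
            "denominator": inventory_size,
            "classes": _with_percent(
                {"annotated": inventory_size - n_novel, "novel": n_novel},
                inventory_size,
            ),
        }
    if partition:
        if "sex" in partition:
            sex = partition["sex"]
            report.sex = {
                "denominator": sex["denominator"],
                "excluded": sex["excluded"],
                "classes": _with_percent(sex["counts"], sex["denominator"]),
            }
        if "tissue" in partition:
            tis = partition["tissue"]
            report.tissue = {
                "denominator": tis["denominator"],
                "classes": _with_percent(tis["counts"], tis["denominator"]),
                "female_stratum": dict(tis.get("female_stratum_counts", {})),
                "female_stratum_size": tis.get("female_stratum_size", 0),
            }
    if orthology_calls:
        section = {}
        for sp, calls in orthology_calls.items():
            n_orth = int((calls["semen_class"] != "no_ortholog").sum())
            section[sp] = {
                "n_orthologs": n_orth,
                "percent_orthologs": percent(n_orth, inventory_size),
                "semen_classes": calls["semen_class"].value_counts().to_dict(),
            }
        report.orthology = section
    if profile is not None:
        report.functional_profile = {k: float(v) for k, v in profile.items()}
    if abundances is not None and len(abundances) >= top_k:
        report.top_k_share = {
            "k": top_k,
            "share_percent": top_k_share(abundances, top_k),
        }
    return report
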