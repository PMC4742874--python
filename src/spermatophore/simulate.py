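"""Seeded synthetic fixture bundles with planted ground truth.

The generator emulates the statistical structure of a seminal-fluid
proteogenomic study: a protein inventory with tryptic-digestible
sequences, mass-spectrometry identification evidence, replicate
RNA-seq unique-read count matrices for whole-body male/female and
testes/MAG libraries, pairwise proteome hit tables with planted
reciprocal-best-hit orthologs among decoy hits, curated SFP/sperm id
lists, and a GO class map.  Every artefact is reproducible from
``(config, seed)`` and is accompanied by a plain-TSV ground-truth
sidecar so downstream classifiers can be scored against what was
planted.

Count model: unique reads are negative-binomial with
``variance = mu + dispersion * mu**2``; ``dispersion = 0`` degenerates
to Poisson.  Per-gene baseline relative abundances are log-normal.
Planted biases multiply the favoured libraries' means by the planted
fold; planted tissue-specific genes have their off-tissue mean forced
to 1/1000 of the on-tissue mean.  Bias is planted only in genes whose
baseline expression clears a detectability floor (a minimum expected
per-library read count), mirroring the fact that bias calls are only
meaningful for genes expressed above the read-count guards of the
classifier.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, NamedTuple, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
import yaml

from . import io as sio
from .digest import DigestParams, digest_trypsin, observable_peptides

__all__ = [
    "LibrarySpec",
    "SimulationConfig",
    "GroundTruth",
    "default_libraries",
    "planted_config",
    "default_config",
    "make_ground_truth",
    "simulate_proteome",
    "gene_lengths_from_proteome",
    "simulate_count_matrix",
    "simulate_evidence",
    "simulate_hit_tables",
    "write_fixture_bundle",
]

SEXES = ("male", "female")
TISSUES = ("whole_body", "testes", "mag")

# Amino-acid background frequencies (roughly proteome-like), with the
# combined K+R frequency held above 10% so tryptic sites are plentiful.
_AA = "ACDEFGHIKLMNPQRSTVWY"
_AA_FREQ = np.array([
    0.080, 0.015, 0.052, 0.062, 0.039, 0.070, 0.022, 0.052, 0.060, 0.090,
    0.023, 0.044, 0.050, 0.040, 0.055, 0.068, 0.055, 0.064, 0.012, 0.047,
])
_AA_FREQ = _AA_FREQ / _AA_FREQ.sum()

GO_VOCAB = [
    "hydrolase activity",
    "ion binding",
    "protein binding",
    "oxidoreductase activity",
    "enzyme inhibitor activity",
    "peptidase regulator activity",
    "transporter activity",
    "structural constituent of cytoskeleton",
    "transferase activity",
    "lipid binding",
    "lyase activity",
    "nucleic acid binding",
]

# Sub-stream indices keyed by purpose so each artefact has its own
# reproducible random stream under a single bundle seed.
_STREAMS = {
    "proteome": 0,
    "truth": 1,
    "counts": 2,
    "evidence": 3,
    "hits": 4,
    "gomap": 5,
    "planting": 6,
}


class LibrarySpec(NamedTuple):
    label: str
    sex: str
    tissue: str
    condition: str


def default_libraries() -> List[LibrarySpec]:
    """Study-shaped design: 2+2 whole-body libraries, 3+3 tissue libraries."""
    libs = [
        LibrarySpec("wb_male_1", "male", "whole_body", "virgin"),
        LibrarySpec("wb_male_2", "male", "whole_body", "virgin"),
        LibrarySpec("wb_female_1", "female", "whole_body", "lactating"),
        LibrarySpec("wb_female_2", "female", "whole_body", "postpartum"),
    ]
    for tissue in ("testes", "mag"):
        for cond in ("teneral", "virgin", "mated"):
            libs.append(LibrarySpec(f"{tissue}_{cond}", "male", tissue, cond))
    return libs


@dataclass
class SimulationConfig:
    """Full description of one synthetic study.

    ``planted_bias`` maps gene id -> (axis, direction, fold) with axis
    in {"sex", "tissue"}, direction a sex or tissue label, and
    fold >= 1.  ``planted_specific`` genes (a subset of the tissue-axis
    planted genes) get near-zero off-tissue expression.
    ``planted_orthologs`` maps species -> {gene id -> subject id};
    ``planted_semen`` maps species -> (sfp id set, sperm id set) in the
    partner species' namespace.
    """

    n_genes: int = 287
    n_novel: int = 23
    libraries: List[LibrarySpec] = field(default_factory=default_libraries)
    mean_depth: float = 1e5
    dispersion: float = 0.1
    planted_bias: Dict[str, Tuple[str, str, float]] = field(default_factory=dict)
    planted_specific: Set[str] = field(default_factory=set)
    planted_orthologs: Dict[str, Dict[str, str]] = field(default_factory=dict)
    planted_semen: Dict[str, Tuple[Set[str], Set[str]]] = field(default_factory=dict)
    seed: int = 0
    # generator shape parameters
    sigma_log: float = 1.0            # log-normal spread of baseline expression
    min_planted_mean: float = 30.0    # detectability floor (expected reads/library)
    low_score_fraction: float = 0.15  # evidence rows given scores <= 54
    seq_len_range: Tuple[int, int] = (100, 400)
    # Share of each library's mapped reads carried by genes outside the
    # simulated inventory.  The inventory emulates a protein inventory's
    # gene subset inside a whole transcriptome: the remaining read mass
    # is constant background, added to the recorded per-library totals
    # so FPKM ratios are not compositionally distorted when many genes
    # carry planted bias.
    background_fraction: float = 0.9

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.n_novel > self.n_genes or self.n_novel < 0:
            raise ValueError("n_novel must lie in [0, n_genes]")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if not 0.0 <= self.background_fraction < 1.0:
            raise ValueError("background_fraction must lie in [0, 1)")
        labels = [lib.label for lib in self.libraries]
        if len(labels) != len(set(labels)):
            raise ValueError("library labels must be unique")
        for lib in self.libraries:
            if lib.sex not in SEXES or lib.tissue not in TISSUES:
                raise ValueError(f"bad library vocabulary in {lib}")
        for gene, (axis, direction, fold) in self.planted_bias.items():
            if fold < 1:
                raise ValueError(f"planted fold for {gene} must be >= 1")
            if axis == "sex" and direction not in SEXES:
                raise ValueError(f"bad sex direction {direction!r}")
            if axis == "tissue" and direction not in ("testes", "mag"):
                raise ValueError(f"bad tissue direction {direction!r}")
            if axis not in ("sex", "tissue"):
                raise ValueError(f"bad axis {axis!r}")
        stray = self.planted_specific - set(self.planted_bias)
        if stray:
            raise ValueError(f"planted_specific genes without planted bias: {sorted(stray)[:5]}")

    def gene_ids(self) -> List[str]:
        return [f"GENE{i:05d}" for i in range(1, self.n_genes + 1)]

    def rng(self, purpose: str) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), _STREAMS[purpose]])

    def to_dict(self) -> dict:
        return {
            "n_genes": self.n_genes,
            "n_novel": self.n_novel,
            "libraries": [list(lib) for lib in self.libraries],
            "mean_depth": float(self.mean_depth),
            "dispersion": float(self.dispersion),
            "n_planted_bias": len(self.planted_bias),
            "n_planted_specific": len(self.planted_specific),
            "species": sorted(self.planted_orthologs),
            "seed": int(self.seed),
            "sigma_log": float(self.sigma_log),
            "min_planted_mean": float(self.min_planted_mean),
            "low_score_fraction": float(self.low_score_fraction),
            "seq_len_range": list(self.seq_len_range),
            "background_fraction": float(self.background_fraction),
        }


@dataclass
class GroundTruth:
    """What was planted, in the same label vocabulary the classifiers emit."""

    genes: pd.DataFrame  # index gene_id: sex_class, tissue_class, novel, abundance_rank
    orthologs: Dict[str, Dict[str, str]]
    semen: Dict[str, Tuple[Set[str], Set[str]]]

    def to_frame(self) -> pd.DataFrame:
        df = self.genes.copy()
        for species, pairs in sorted(self.orthologs.items()):
            df[f"ortholog_{species}"] = [pairs.get(g, "") for g in df.index]
            sfp, sperm = self.semen.get(species, (set(), set()))
            classes = []
            for g in df.index:
                ortho = pairs.get(g)
                if ortho is None:
                    classes.append("no_ortholog")
                elif ortho in sfp and ortho in sperm:
                    classes.append("both")
                elif ortho in sfp:
                    classes.append("SFP")
                elif ortho in sperm:
                    classes.append("sperm")
                else:
                    classes.append("neither")
            df[f"semen_{species}"] = classes
        return df


def make_ground_truth(config: SimulationConfig) -> GroundTruth:
    rng = config.rng("truth")
    genes = config.gene_ids()
    novel = set(rng.choice(genes, size=config.n_novel, replace=False)) if config.n_novel else set()
    sex_class, tissue_class = [], []
    for g in genes:
        axis, direction, fold = config.planted_bias.get(g, (None, None, 1.0))
        if axis == "sex" and fold > 1:
            sex_class.append(f"{direction}_biased")
        else:
            sex_class.append("unbiased")
        if axis == "tissue" and fold > 1:
            suffix = "specific" if g in config.planted_specific else "biased"
            tissue_class.append(f"{direction}_{suffix}")
        else:
            tissue_class.append("unbiased")
    rank = rng.permutation(len(genes)) + 1
    df = pd.DataFrame(
        {
            "sex_class": sex_class,
            "tissue_class": tissue_class,
            "novel": [g in novel for g in genes],
            "abundance_rank": rank,
        },
        index=pd.Index(genes, name="gene_id"),
    )
    return GroundTruth(df, dict(config.planted_orthologs), dict(config.planted_semen))


class ProteinRecord(NamedTuple):
    protein_id: str
    sequence: str
    novel: bool


def simulate_proteome(
    config: SimulationConfig, truth: GroundTruth | None = None
) -> List[ProteinRecord]:
    """Random amino-acid sequences with plentiful tryptic sites.

    Deterministic for a fixed (config, seed); the novelty flags mark
    exactly ``n_novel`` proteins (those flagged in the ground truth).
    """
    if truth is None:
        truth = make_ground_truth(config)
    rng = config.rng("proteome")
    lo, hi = config.seq_len_range
    if lo < 30:
        raise ValueError("sequences must be at least 30 residues")
    records = []
    aa = np.array(list(_AA))
    for gene in config.gene_ids():
        length = int(rng.integers(lo, hi + 1))
        seq = "M" + "".join(rng.choice(aa, size=length - 1, p=_AA_FREQ))
        records.append(ProteinRecord(gene, seq, bool(truth.genes.at[gene, "novel"])))
    return records


def gene_lengths_from_proteome(proteome: Sequence[ProteinRecord]) -> pd.Series:
    """Exonic gene length in bp: three nucleotides per residue."""
    return pd.Series(
        {rec.protein_id: 3 * len(rec.sequence) for rec in proteome}, name="gene_length_bp"
    ).rename_axis("gene_id")


def _baseline_relative_abundance(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Log-normal baselines; planted genes rejection-sampled above the floor."""
    sigma = config.sigma_log
    raw = rng.lognormal(mean=0.0, sigma=sigma, size=config.n_genes)
    # expected normalised value of a raw draw x is ~ x / (n * exp(sigma^2/2))
    floor_raw = (
        (config.min_planted_mean / config.mean_depth)
        * config.n_genes
        * np.exp(sigma**2 / 2.0)
    )
    planted_idx = [
        i
        for i, g in enumerate(config.gene_ids())
        if config.planted_bias.get(g, (None, None, 1.0))[2] > 1
    ]
    for i in planted_idx:
        tries = 0
        while raw[i] < floor_raw and tries < 1000:
            raw[i] = rng.lognormal(mean=0.0, sigma=sigma)
            tries += 1
        raw[i] = max(raw[i], floor_raw)
    return raw / raw.sum()


def simulate_count_matrix(
    config: SimulationConfig, truth: GroundTruth | None = None
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Overdispersed unique-read counts plus per-library metadata.

    Returns ``(counts, meta)``; counts are genes x libraries.  Each
    library's ``total_mapped_reads`` is its realised column sum plus
    the constant background read mass implied by
    ``background_fraction`` (reads mapped to genes outside the
    simulated inventory).
    """
    if not config.libraries:
        raise ValueError("library list is empty")
    if truth is None:
        truth = make_ground_truth(config)
    rng = config.rng("counts")
    genes = config.gene_ids()
    rel = _baseline_relative_abundance(config, rng)

    mu = np.empty((config.n_genes, len(config.libraries)))
    for j, lib in enumerate(config.libraries):
        mult = np.ones(config.n_genes)
        for i, g in enumerate(genes):
            planted = config.planted_bias.get(g)
            if planted is None:
                continue
            axis, direction, fold = planted
            if axis == "sex":
                if lib.sex == direction:
                    mult[i] = fold
            else:  # tissue axis only touches the dissected-tissue libraries
                if lib.tissue == direction:
                    mult[i] = fold
                elif lib.tissue in ("testes", "mag") and g in config.planted_specific:
                    mult[i] = fold / 1000.0  # off-tissue forced near zero
        mu[:, j] = config.mean_depth * rel * mult

    if config.dispersion == 0:
        counts = rng.poisson(mu)
    else:
        r = 1.0 / config.dispersion
        p = r / (r + mu)
        counts = rng.negative_binomial(r, p)
    counts_df = pd.DataFrame(
        counts, index=pd.Index(genes, name="gene_id"),
        columns=[lib.label for lib in config.libraries],
    )
    meta = pd.DataFrame(
        {
            "label": [lib.label for lib in config.libraries],
            "sex": [lib.sex for lib in config.libraries],
            "tissue": [lib.tissue for lib in config.libraries],
            "condition": [lib.condition for lib in config.libraries],
            "total_mapped_reads": np.maximum(
                counts_df.sum(axis=0).to_numpy()
                + int(round(
                    config.mean_depth
                    * config.background_fraction
                    / (1.0 - config.background_fraction)
                )),
                1,
            ),
        }
    )
    return counts_df, meta


def default_abundance_plan(
    config: SimulationConfig, truth: GroundTruth
) -> Dict[str, float]:
    """Observed-peptide fraction per protein, decreasing in abundance rank."""
    n = config.n_genes
    plan = {}
    for g in config.gene_ids():
        rank = int(truth.genes.at[g, "abundance_rank"])
        plan[g] = 0.05 + 0.85 * (n - rank) / max(n - 1, 1)
    return plan


def simulate_evidence(
    config: SimulationConfig,
    truth: GroundTruth | None = None,
    abundance_plan: Mapping[str, float] | None = None,
    proteome: Sequence[ProteinRecord] | None = None,
    digest_params: DigestParams | None = None,
) -> pd.DataFrame:
    """Identification evidence table (protein_id, score, n_observed).

    Observed distinct-peptide counts are binomial draws over each
    protein's observable peptides with the planned per-protein
    fraction; a configured fraction of rows receives sub-threshold
    scores (<= 54) to exercise the identification filter.
    """
    if truth is None:
        truth = make_ground_truth(config)
    if proteome is None:
        proteome = simulate_proteome(config, truth)
    if abundance_plan is None:
        abundance_plan = default_abundance_plan(config, truth)
    params = digest_params or DigestParams()
    rng = config.rng("evidence")
    rows = []
    for rec in proteome:
        frac = float(abundance_plan[rec.protein_id])
        if not 0.0 <= frac <= 1.0:
            raise ValueError(f"abundance plan fraction {frac} outside [0, 1]")
        observable = len(observable_peptides(rec.sequence, params))
        n_obs = int(rng.binomial(observable, frac)) if observable else 0
        rows.append({"protein_id": rec.protein_id, "n_observed": n_obs})
    n_low = int(round(config.low_score_fraction * len(rows)))
    low_idx = set(rng.choice(len(rows), size=n_low, replace=False)) if n_low else set()
    for i, row in enumerate(rows):
        if i in low_idx:
            row["score"] = float(np.round(rng.uniform(20.0, 54.0), 2))
        else:
            row["score"] = float(np.round(rng.uniform(55.0, 400.0), 2))
    return pd.DataFrame(rows, columns=["protein_id", "score", "n_observed"])


def _hit_row(rng, q, s, evalue, bitscore=None):
    length = int(rng.integers(80, 400))
    mismatch = int(rng.integers(0, length // 4 + 1))
    return {
        "qseqid": q,
        "sseqid": s,
        "pident": float(np.round(100.0 * (length - mismatch) / length, 2)),
        "length": length,
        "mismatch": mismatch,
        "gapopen": int(rng.integers(0, 5)),
        "qstart": 1,
        "qend": length,
        "sstart": 1,
        "send": length,
        "evalue": float(evalue),
        "bitscore": float(bitscore if bitscore is not None else np.round(rng.uniform(120, 900), 1)),
    }


def simulate_hit_tables(
    config: SimulationConfig, truth: GroundTruth | None = None
) -> Dict[str, Tuple[pd.DataFrame, pd.DataFrame]]:
    """Forward/reverse 12-column hit tables per species.

    Every planted ortholog pair appears as a mutual best hit below the
    e-value threshold.  Decoys include one-way best hits (the reverse
    best points elsewhere), hits entirely above the threshold, and tied
    e-values that require deterministic tie-breaking.
    """
    if truth is None:
        truth = make_ground_truth(config)
    rng = config.rng("hits")
    genes = config.gene_ids()
    tables: Dict[str, Tuple[pd.DataFrame, pd.DataFrame]] = {}
    for species in sorted(config.planted_orthologs):
        pairs = config.planted_orthologs[species]
        fwd_rows, rev_rows = [], []
        planted_genes = sorted(pairs)
        for g in planted_genes:
            s = pairs[g]
            e = 10.0 ** -rng.uniform(20, 80)
            fwd_rows.append(_hit_row(rng, g, s, e))
            rev_rows.append(_hit_row(rng, s, g, e))
            # a clearly worse secondary hit in each direction
            decoy = f"{species[:3].upper()}_DEC{rng.integers(0, 10**6):06d}"
            fwd_rows.append(_hit_row(rng, g, decoy, e * 1e5, bitscore=50.0))
            rev_rows.append(_hit_row(rng, s, f"{g}_alt", e * 1e5, bitscore=50.0))
        unplanted = [g for g in genes if g not in pairs]
        rng.shuffle(unplanted)
        # one-way decoys: forward best survives but the reverse best points
        # back at a planted gene, so no pair forms
        n_oneway = min(len(unplanted), max(1, len(genes) // 20))
        for g in unplanted[:n_oneway]:
            y = f"{species[:3].upper()}_ONE{rng.integers(0, 10**6):06d}"
            fwd_rows.append(_hit_row(rng, g, y, 10.0 ** -rng.uniform(15, 40)))
            other = planted_genes[int(rng.integers(0, len(planted_genes)))] if planted_genes else f"{g}_x"
            rev_rows.append(_hit_row(rng, y, other, 10.0 ** -rng.uniform(15, 40)))
        # hits above the threshold: must never produce a best hit
        weak = unplanted[n_oneway : n_oneway + max(1, len(genes) // 30)]
        for g in weak:
            fwd_rows.append(
                _hit_row(rng, g, f"{species[:3].upper()}_WEAK{rng.integers(0, 10**6):06d}",
                         10.0 ** -rng.uniform(3, 9))
            )
        # tie decoys: equal e-values resolved by bit score, then subject id
        ties = unplanted[n_oneway + len(weak) : n_oneway + len(weak) + 2]
        if len(ties) >= 1:
            g = ties[0]
            e = 1e-30
            fwd_rows.append(_hit_row(rng, g, "TIE_B", e, bitscore=200.0))
            fwd_rows.append(_hit_row(rng, g, "TIE_A", e, bitscore=180.0))
        if len(ties) >= 2:
            g = ties[1]
            e = 1e-25
            fwd_rows.append(_hit_row(rng, g, "TIE_D", e, bitscore=150.0))
            fwd_rows.append(_hit_row(rng, g, "TIE_C", e, bitscore=150.0))
        from .orthology import BLAST_COLUMNS

        tables[species] = (
            pd.DataFrame(fwd_rows, columns=BLAST_COLUMNS),
            pd.DataFrame(rev_rows, columns=BLAST_COLUMNS),
        )
    return tables


def _go_map(config: SimulationConfig, truth: GroundTruth) -> Dict[str, Set[str]]:
    rng = config.rng("gomap")
    out: Dict[str, Set[str]] = {}
    for g in config.gene_ids():
        if truth.genes.at[g, "novel"]:
            continue  # novel proteins have no GO annotation by definition
        if rng.random() < 0.18:
            continue  # annotated elsewhere but without a Level-III class
        k = int(rng.integers(1, 4))
        out[g] = set(rng.choice(GO_VOCAB, size=k, replace=False))
    return out


def planted_config(
    seed: int,
    n_genes: int = 2000,
    fold: float = 10.0,
    mean_depth: float = 1e5,
    dispersion: float = 0.1,
    n_sex_male: int = 30,
    n_sex_female: int = 20,
    n_testes_biased: int = 25,
    n_mag_biased: int = 15,
    n_testes_specific: int = 20,
    n_novel: Optional[int] = None,
    ortholog_fraction: float = 0.7,
    species: Sequence[str] = ("dmel", "mdom"),
) -> SimulationConfig:
    """Config with disjoint planted gene sets of the given sizes."""
    rng = np.random.default_rng([int(seed), _STREAMS["planting"]])
    if n_novel is None:
        n_novel = max(1, int(round(0.08 * n_genes)))
    gene_ids = [f"GENE{i:05d}" for i in range(1, n_genes + 1)]
    n_planted = n_sex_male + n_sex_female + n_testes_biased + n_mag_biased + n_testes_specific
    if n_planted > n_genes:
        raise ValueError("more planted genes than genes")
    chosen = list(rng.choice(gene_ids, size=n_planted, replace=False))
    planted_bias: Dict[str, Tuple[str, str, float]] = {}
    specific: Set[str] = set()
    cursor = 0
    for count, axis, direction, is_specific in (
        (n_sex_male, "sex", "male", False),
        (n_sex_female, "sex", "female", False),
        (n_testes_biased, "tissue", "testes", False),
        (n_mag_biased, "tissue", "mag", False),
        (n_testes_specific, "tissue", "testes", True),
    ):
        for g in chosen[cursor : cursor + count]:
            planted_bias[g] = (axis, direction, float(fold))
            if is_specific:
                specific.add(g)
        cursor += count
    orthologs: Dict[str, Dict[str, str]] = {}
    semen: Dict[str, Tuple[Set[str], Set[str]]] = {}
    for sp in species:
        n_orth = int(round(ortholog_fraction * n_genes))
        with_orth = rng.choice(gene_ids, size=n_orth, replace=False)
        mapping = {
            g: f"{sp[:3].upper()}_{i:05d}" for i, g in enumerate(sorted(with_orth), 1)
        }
        subjects = list(mapping.values())
        n_sfp = max(1, len(subjects) // 10)
        n_sperm = max(1, len(subjects) // 4)
        picked = rng.choice(subjects, size=min(n_sfp + n_sperm, len(subjects)), replace=False)
        semen[sp] = (set(picked[:n_sfp]), set(picked[n_sfp:]))
        orthologs[sp] = mapping
    return SimulationConfig(
        n_genes=n_genes,
        n_novel=n_novel,
        mean_depth=mean_depth,
        dispersion=dispersion,
        planted_bias=planted_bias,
        planted_specific=specific,
        planted_orthologs=orthologs,
        planted_semen=semen,
        seed=int(seed),
    )


def default_config(seed: int = 0) -> SimulationConfig:
    """Study-shaped default: 287 genes with bias planted in the
    proportions the tsetse spermatophore inventory showed."""
    return planted_config(
        seed,
        n_genes=287,
        fold=10.0,
        n_sex_male=57,
        n_sex_female=10,
        n_testes_biased=60,
        n_mag_biased=23,
        n_testes_specific=17,
        n_novel=23,
    )


def grouping_from_meta(meta: pd.DataFrame) -> Dict[str, str]:
    """Map each library to its classifier group (male/female/testes/mag)."""
    if "label" in meta.columns:
        meta = meta.set_index("label")
    grouping = {}
    for label, row in meta.iterrows():
        if row["tissue"] == "whole_body":
            grouping[label] = row["sex"]
        else:
            grouping[label] = row["tissue"]
    return grouping


def write_fixture_bundle(config: SimulationConfig, out_dir) -> dict:
    """Write the full fixture bundle and return its manifest.

    The bundle contains the proteome FASTA, evidence/counts/lengths/
    metadata/GO-map/truth TSVs, per-species forward+reverse hit tables
    and SFP/sperm id lists, plus a YAML manifest recording the config,
    seed and a SHA-256 checksum per file.  Identical (config, seed)
    produce byte-identical bundles.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        (out / "hits").mkdir(exist_ok=True)
        (out / "semen").mkdir(exist_ok=True)
    except OSError as exc:
        raise OSError(f"destination {out} is not writable: {exc}") from exc

    truth = make_ground_truth(config)
    proteome = simulate_proteome(config, truth)
    sio.write_fasta(
        {r.protein_id: r.sequence for r in proteome},
        out / "proteome.fasta",
        descriptions={r.protein_id: "novel" for r in proteome if r.novel},
    )
    lengths = gene_lengths_from_proteome(proteome)
    lengths.to_frame().to_csv(out / "gene_lengths.tsv", sep="\t")
    counts, meta = simulate_count_matrix(config, truth)
    counts.to_csv(out / "counts.tsv", sep="\t")
    meta.to_csv(out / "library_meta.tsv", sep="\t", index=False)
    evidence = simulate_evidence(config, truth, proteome=proteome)
    evidence.to_csv(out / "evidence.tsv", sep="\t", index=False)
    go_map = _go_map(config, truth)
    sio.write_go_map(go_map, out / "go_map.tsv")
    for species, (fwd, rev) in simulate_hit_tables(config, truth).items():
        sio.write_hit_table(fwd, out / "hits" / f"{species}_forward.tsv")
        sio.write_hit_table(rev, out / "hits" / f"{species}_reverse.tsv")
    for species, (sfp, sperm) in sorted(config.planted_semen.items()):
        sio.write_id_list(sorted(sfp), out / "semen" / f"{species}_sfp.txt")
        sio.write_id_list(sorted(sperm), out / "semen" / f"{species}_sperm.txt")
    truth.to_frame().to_csv(out / "truth.tsv", sep="\t")

    files = sorted(
        str(p.relative_to(out)) for p in out.rglob("*") if p.is_file() and p.name != "manifest.yaml"
    )
    checksums = {
        f: hashlib.sha256((out / f).read_bytes()).hexdigest() for f in files
    }
    manifest = {
        "config": config.to_dict(),
        "seed": int(config.seed),
        "files": checksums,
        "bundle_checksum": hashlib.sha256(
            "".join(f"{f}:{checksums[f]}" for f in files).encode()
        ).hexdigest(),
    }
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return manifest
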