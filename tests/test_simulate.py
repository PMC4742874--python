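"""Synthetic fixture generator: determinism, planted structure, bundles."""

import numpy as np
import pandas as pd
import pytest

from spermatophore.orthology import OrthologyParams, rbh, read_hit_table
from spermatophore.simulate import (
    SimulationConfig,
    default_config,
    make_ground_truth,
    planted_config,
    simulate_count_matrix,
    simulate_evidence,
    simulate_hit_tables,
    simulate_proteome,
    write_fixture_bundle,
)


class TestProteome:
    def test_seeded_determinism_and_seed_sensitivity(self, small_config):
        a = simulate_proteome(small_config)
        b = simulate_proteome(small_config)
        assert a == b
        other = planted_config(seed=small_config.seed + 1, n_genes=small_config.n_genes,
                               n_sex_male=0, n_sex_female=0, n_testes_biased=0,
                               n_mag_biased=0, n_testes_specific=0)
        c = simulate_proteome(other)
        assert any(x.sequence != y.sequence for x, y in zip(a, c))

    def test_novelty_count_and_sequence_shape(self):
        cfg = planted_config(seed=2, n_genes=10, n_sex_male=0, n_sex_female=0,
                             n_testes_biased=0, n_mag_biased=0, n_testes_specific=0,
                             n_novel=3)
        records = simulate_proteome(cfg)
        assert sum(r.novel for r in records) == 3
        assert all(len(r.sequence) >= 30 for r in records)
        kr_rich = sum(
            1 for r in records if sum(r.sequence.count(x) for x in "KR") >= 2
        )
        assert kr_rich >= 0.8 * len(records)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_genes=5, n_novel=9)
        with pytest.raises(ValueError):
            SimulationConfig(planted_bias={"GENE00001": ("sex", "male", 0.5)})
        with pytest.raises(ValueError):
            SimulationConfig(planted_specific={"GENE00001"})


class TestCountMatrix:
    def test_poisson_limit_at_zero_dispersion(self):
        """dispersion=0: per-gene variance ~ mean across many replicates."""
        libs = [("rep%03d" % i, "male", "whole_body", "c") for i in range(1000)]
        from spermatophore.simulate import LibrarySpec

        cfg = SimulationConfig(
            n_genes=20, n_novel=0, dispersion=0.0, mean_depth=2e4,
            libraries=[LibrarySpec(*l) for l in libs], seed=5,
        )
        counts, _ = simulate_count_matrix(cfg, make_ground_truth(cfg))
        arr = counts.to_numpy(float)
        means = arr.mean(axis=1)
        variances = arr.var(axis=1, ddof=1)
        big = means > 50  # stable ratio needs reasonable counts
        ratio = variances[big] / means[big]
        assert np.all(np.abs(ratio - 1.0) < 0.15)

    def test_overdispersion_raises_variance(self):
        from spermatophore.simulate import LibrarySpec

        libs = [LibrarySpec("rep%03d" % i, "male", "whole_body", "c") for i in range(500)]
        cfg = SimulationConfig(n_genes=20, n_novel=0, dispersion=0.5,
                               mean_depth=2e4, libraries=libs, seed=6)
        counts, _ = simulate_count_matrix(cfg, make_ground_truth(cfg))
        arr = counts.to_numpy(float)
        means, variances = arr.mean(axis=1), arr.var(axis=1, ddof=1)
        big = means > 100
        assert np.all(variances[big] / means[big] > 2.0)

    def test_planted_fold_realised_in_fpkm_ratio(self):
        """fold=10 male bias yields realized male/female FPKM ratio > 5."""
        from spermatophore.expression import compute_fpkm, pool_groups
        from spermatophore.simulate import (
            gene_lengths_from_proteome,
            grouping_from_meta,
        )

        hit = total = 0
        n_seeds = 25
        for seed in range(n_seeds):
            cfg = planted_config(seed, n_genes=200, n_sex_male=5, n_sex_female=0,
                                 n_testes_biased=0, n_mag_biased=0, n_testes_specific=0)
            truth = make_ground_truth(cfg)
            prot = simulate_proteome(cfg, truth)
            counts, meta = simulate_count_matrix(cfg, truth)
            fpkm = compute_fpkm(counts, gene_lengths_from_proteome(prot), meta)
            means, _ = pool_groups(fpkm, counts, grouping_from_meta(meta))
            planted = truth.genes.index[truth.genes.sex_class == "male_biased"]
            ratio = means.loc[planted, "male"] / means.loc[planted, "female"]
            hit += int((ratio > 5).sum())
            total += len(planted)
        assert hit / total >= 0.95

    def test_specific_genes_near_zero_off_tissue(self, small_config, small_truth):
        counts, _ = simulate_count_matrix(small_config, small_truth)
        specific = sorted(small_config.planted_specific)
        mag_cols = [l.label for l in small_config.libraries if l.tissue == "mag"]
        testes_cols = [l.label for l in small_config.libraries if l.tissue == "testes"]
        off = counts.loc[specific, mag_cols].sum(axis=1)
        on = counts.loc[specific, testes_cols].sum(axis=1)
        assert (off < on / 50).all()

    def test_empty_library_list_rejected(self):
        cfg = SimulationConfig(n_genes=3, n_novel=0, libraries=[])
        with pytest.raises(ValueError):
            simulate_count_matrix(cfg, make_ground_truth(cfg))


class TestEvidence:
    def test_plan_fraction_extremes(self, small_config, small_truth, small_proteome):
        from spermatophore.digest import DigestParams, observable_peptides

        plan0 = {r.protein_id: 0.0 for r in small_proteome}
        ev = simulate_evidence(small_config, small_truth, plan0, small_proteome)
        assert (ev["n_observed"] == 0).all()
        plan1 = {r.protein_id: 1.0 for r in small_proteome}
        ev = simulate_evidence(small_config, small_truth, plan1, small_proteome)
        for rec in small_proteome:
            observable = len(observable_peptides(rec.sequence, DigestParams()))
            got = int(ev.set_index("protein_id").at[rec.protein_id, "n_observed"])
            assert got == observable

    def test_half_fraction_mean(self, small_config, small_truth, small_proteome):
        from spermatophore.digest import DigestParams, observable_peptides

        plan = {r.protein_id: 0.5 for r in small_proteome}
        ev = simulate_evidence(small_config, small_truth, plan, small_proteome)
        obs = ev.set_index("protein_id")["n_observed"]
        fracs = []
        for rec in small_proteome:
            observable = len(observable_peptides(rec.sequence, DigestParams()))
            if observable:
                fracs.append(obs[rec.protein_id] / observable)
        assert 0.4 <= np.mean(fracs) <= 0.6

    def test_low_score_fraction_exercises_filter(self, small_config, small_truth, small_proteome):
        ev = simulate_evidence(small_config, small_truth, proteome=small_proteome)
        n_low = (ev["score"] <= 54).sum()
        assert n_low == round(small_config.low_score_fraction * len(ev))


class TestHitTables:
    def test_planted_pairs_are_recovered_decoys_are_not(self, small_config, small_truth):
        tables = simulate_hit_tables(small_config, small_truth)
        for species, (fwd, rev) in tables.items():
            pairs = rbh(fwd, rev, OrthologyParams())
            planted = sorted(small_config.planted_orthologs[species].items())
            assert pairs == planted

    def test_tables_round_trip_through_reader(self, small_config, small_truth, tmp_path):
        from spermatophore.io import write_hit_table

        tables = simulate_hit_tables(small_config, small_truth)
        species = sorted(tables)[0]
        fwd, _ = tables[species]
        path = tmp_path / "fwd.tsv"
        write_hit_table(fwd, path)
        parsed = read_hit_table(path)
        assert list(parsed["qseqid"]) == list(fwd["qseqid"])
        assert np.allclose(parsed["evalue"], fwd["evalue"])


class TestBundle:
    def test_all_artifact_kinds_present(self, bundle_dir, small_config):
        for name in [
            "proteome.fasta", "evidence.tsv", "counts.tsv", "gene_lengths.tsv",
            "library_meta.tsv", "go_map.tsv", "truth.tsv", "manifest.yaml",
        ]:
            assert (bundle_dir / name).exists(), name
        for species in small_config.planted_orthologs:
            assert (bundle_dir / "hits" / f"{species}_forward.tsv").exists()
            assert (bundle_dir / "hits" / f"{species}_reverse.tsv").exists()
            assert (bundle_dir / "semen" / f"{species}_sfp.txt").exists()
            assert (bundle_dir / "semen" / f"{species}_sperm.txt").exists()

    def test_rerun_is_byte_identical(self, small_config, tmp_path):
        m1 = write_fixture_bundle(small_config, tmp_path / "a")
        m2 = write_fixture_bundle(small_config, tmp_path / "b")
        assert m1["bundle_checksum"] == m2["bundle_checksum"]

    def test_referential_integrity(self, bundle_dir):
        from spermatophore.io import read_fasta

        proteome_ids = set(read_fasta(bundle_dir / "proteome.fasta"))
        truth = pd.read_csv(bundle_dir / "truth.tsv", sep="\t", index_col=0)
        counts = pd.read_csv(bundle_dir / "counts.tsv", sep="\t", index_col=0)
        evidence = pd.read_csv(bundle_dir / "evidence.tsv", sep="\t")
        assert set(truth.index) <= proteome_ids
        assert set(counts.index) <= proteome_ids
        assert set(evidence["protein_id"]) <= proteome_ids
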