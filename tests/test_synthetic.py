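"""The synthetic-data generator: determinism, injected truth, calibration."""

import filecmp
from pathlib import Path

import numpy as np
import pytest

from coniferdiv.codon import find_longest_orf
from coniferdiv.convergence import overlap_analysis
from coniferdiv.synthetic import (
    ConfigError,
    SyntheticConfig,
    generate_annotation_assignments,
    generate_species_dataset,
    write_species_dataset,
)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs,field",
        [
            (dict(nb_dispersion=0.0), "nb_dispersion"),
            (dict(psg_fraction=1.5), "psg_fraction"),
            (dict(snp_rate_per_species=(0.001, -0.1)), "snp_rate_per_species"),
            (dict(n_megagametophytes=0), "n_megagametophytes"),
            (dict(paralog_snp_rate=-0.2), "paralog_snp_rate"),
        ],
    )
    def test_errors_name_the_field(self, kwargs, field):
        with pytest.raises(ConfigError, match=field):
            SyntheticConfig(n_species=2, n_transcripts_per_species=10, **kwargs)

    def test_rate_list_length_must_match_species(self):
        with pytest.raises(ConfigError, match="snp_rate_per_species"):
            SyntheticConfig(n_species=3, snp_rate_per_species=(0.005,))


class TestSpeciesDataset:
    def test_fixed_seed_is_byte_identical(self, tmp_path):
        cfg = SyntheticConfig(n_species=2, n_transcripts_per_species=40, seed=1)
        dirs = []
        for name in ("a", "b"):
            ds = generate_species_dataset(cfg, 0)
            d = tmp_path / name
            write_species_dataset(ds, d)
            dirs.append(d)
        files = sorted(p.name for p in dirs[0].iterdir())
        match, mismatch, errors = filecmp.cmpfiles(*dirs, files, shallow=False)
        assert mismatch == [] and errors == [] and match == files

    def test_different_seed_same_schema(self, tmp_path):
        out = {}
        for seed in (1, 2):
            cfg = SyntheticConfig(n_species=1, n_transcripts_per_species=30, seed=seed)
            ds = generate_species_dataset(cfg, 0)
            out[seed] = ds
        assert set(out[1].transcripts) == set(out[2].transcripts)  # same ids
        assert {v.key for v in out[1].embryo_variants} != {
            v.key for v in out[2].embryo_variants
        }

    def test_orfs_are_recoverable_and_long(self, small_dataset):
        n_long = 0
        for tid, seq in small_dataset.transcripts.items():
            orf = find_longest_orf(seq, tid)
            assert orf is not None
            truth = small_dataset.orfs[tid]
            assert (orf.start, orf.end) == (truth.start, truth.end)
            n_long += orf.length >= 300
        assert n_long >= 0.9 * len(small_dataset.transcripts)

    def test_paralogs_present_in_megagametophytes(self, small_dataset):
        mega_keys = {
            v.key for mset in small_dataset.megagametophyte_variants for v in mset
        }
        embryo_keys = {v.key for v in small_dataset.embryo_variants}
        truth = small_dataset.truth.true_paralog_snp_ids
        assert truth <= mega_keys
        assert truth <= embryo_keys
        assert mega_keys == truth  # megagametophytes carry only paralog sites

    def test_zero_paralog_rate_gives_disjoint_sets(self):
        cfg = SyntheticConfig(
            n_species=1, n_transcripts_per_species=50, paralog_snp_rate=0.0, seed=5
        )
        ds = generate_species_dataset(cfg, 0)
        mega_keys = {v.key for m in ds.megagametophyte_variants for v in m}
        assert mega_keys & {v.key for v in ds.embryo_variants} == set()

    def test_variant_refs_match_transcripts(self, small_dataset):
        for v in small_dataset.embryo_variants[:200]:
            assert small_dataset.transcripts[v.transcript_id][v.position] == v.ref

    def test_mean_snp_count_matches_configured_rate(self):
        """Monte-Carlo check of the generator against its own expectation:
        a rate tuned for ~6 SNPs per transcript lands within [5.7, 6.3]."""
        mean_sites = 894.0  # expected coding sites under the default lengths
        cfg = SyntheticConfig(
            n_species=1, n_transcripts_per_species=2000,
            snp_rate_per_species=(6.0 / mean_sites,),
            psg_fraction=0.0, paralog_snp_rate=0.0,
            depth_effect_exponent=0.0, seed=13,
        )
        ds = generate_species_dataset(cfg, 0)
        mean = len(ds.embryo_variants) / cfg.n_transcripts_per_species
        assert 5.7 <= mean <= 6.3

    def test_psg_genes_receive_nonsynonymous_excess(self):
        cfg = SyntheticConfig(
            n_species=1, n_transcripts_per_species=300,
            snp_rate_per_species=(0.02,), psg_fraction=0.5,
            psg_nonsyn_multiplier=5.0, paralog_snp_rate=0.0, seed=9,
        )
        ds = generate_species_dataset(cfg, 0)
        truth = ds.truth.genes.set_index("gene_id")["true_psg"]
        counts = {}
        for v in ds.embryo_variants:
            counts[v.transcript_id] = counts.get(v.transcript_id, 0) + 1
        psg_mean = np.mean([counts.get(g, 0) for g in truth.index[truth]])
        null_mean = np.mean([counts.get(g, 0) for g in truth.index[~truth]])
        assert psg_mean > 2.0 * null_mean  # tripled A-rate inflates totals


class TestAnnotations:
    def test_realized_shared_fractions_match_profile(self):
        cfg = SyntheticConfig(
            n_species=7, n_transcripts_per_species=1000, seed=21,
            convergence_profile=(0.65, 0.97, 0.91),
        )
        genes = {
            cfg.species_name(i): [f"{cfg.species_name(i)}_g{j}" for j in range(1000)]
            for i in range(7)
        }
        sets, table = generate_annotation_assignments(cfg, genes)
        for level, target in zip(("orthogroup", "family", "process"), (0.65, 0.97, 0.91)):
            ov = overlap_analysis(sets[level])
            assert abs(ov.shared_pct / 100.0 - target) <= 0.05, level

    def test_hierarchy_is_nested(self):
        cfg = SyntheticConfig(n_species=3, n_transcripts_per_species=200, seed=2)
        genes = {f"sp{i+1}": [f"sp{i+1}_g{j}" for j in range(200)] for i in range(3)}
        _, table = generate_annotation_assignments(cfg, genes)
        # all genes of an orthogroup share one family
        assert (table.groupby("orthogroup_id")["family_id"].nunique() == 1).all()
        # every family maps to at least one process
        assert table.groupby("family_id")["process_id"].nunique().min() >= 1

    @pytest.mark.parametrize("q", [0.0, 1.0])
    def test_degenerate_profiles(self, q):
        cfg = SyntheticConfig(
            n_species=3, n_transcripts_per_species=300, seed=4,
            convergence_profile=(q, q, q),
        )
        genes = {f"sp{i+1}": [f"sp{i+1}_g{j}" for j in range(300)] for i in range(3)}
        sets, _ = generate_annotation_assignments(cfg, genes)
        for level_sets in sets.values():
            ov = overlap_analysis(level_sets)
            if q == 1.0:
                assert ov.in_all_count == ov.universe_size  # in every species
            else:
                assert ov.shared_count == 0  # pairwise intersections empty

    def test_empty_gene_sets_raise(self):
        cfg = SyntheticConfig(n_species=2, n_transcripts_per_species=10, seed=1)
        with pytest.raises(ValueError):
            generate_annotation_assignments(cfg, {"sp1": ["g1"], "sp2": []})
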