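"""Genotype simulator: mosaic LD, drift divergence, MAF filter, PLINK I/O."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from crosspred.popsim import (PopSimConfig, GenotypePanel,
                              simulate_base_haplotypes, evolve_populations,
                              apply_maf_filter, simulate_panel,
                              write_genotypes, read_genotypes)


def small_config(**kw):
    defaults = dict(n_individuals=(40, 20, 20), within_pop_ne=(30, 20, 20),
                    n_snps_per_chromosome=100, divergence_generations=5,
                    n_founder_haplotypes=4, seed=1)
    defaults.update(kw)
    return PopSimConfig(**defaults)


class TestConfig:
    @pytest.mark.parametrize("bad", [
        dict(maf_threshold=0.5), dict(maf_threshold=-0.01),
        dict(n_founder_haplotypes=1), dict(n_snps_per_chromosome=0),
        dict(population_labels=("A", "A", "B")),
        dict(n_individuals=(10, 20)),
    ])
    def test_invalid_rejected(self, bad):
        with pytest.raises(ValueError):
            small_config(**bad)

    def test_key_value_file_round_trip(self, tmp_path):
        path = tmp_path / "sim.cfg"
        path.write_text("n_individuals = 40,20,20\nwithin_pop_ne = 30,20,20\n"
                        "n_snps_per_chromosome = 100  # pre-filter\n"
                        "n_founder_haplotypes = 4\nseed = 9\n")
        cfg = PopSimConfig.from_file(path)
        assert cfg.n_individuals == (40, 20, 20)
        assert cfg.seed == 9


class TestBaseHaplotypes:
    def test_ld_decays_with_distance(self):
        """Adjacent SNPs share founder blocks, distant ones do not."""
        cfg = small_config(n_chromosomes=1, chromosome_labels=("13",),
                          n_snps_per_chromosome=100, n_founder_haplotypes=4)
        pool, snp_map = simulate_base_haplotypes(cfg, n_haplotypes=300)
        gpos = snp_map["genetic_position"].to_numpy()
        X = pool.astype(float)
        Xc = X - X.mean(0)
        sd = X.std(0)
        keep = sd > 0

        def mean_r2(pairs):
            vals = []
            for a, b in pairs:
                if keep[a] and keep[b]:
                    r = (Xc[:, a] * Xc[:, b]).mean() / (sd[a] * sd[b])
                    vals.append(r * r)
            return np.mean(vals)

        adjacent = [(j, j + 1) for j in range(99)]
        distant = [(a, b) for a in range(100) for b in range(a + 1, 100)
                   if gpos[b] - gpos[a] > 0.5][:300]
        assert mean_r2(adjacent) > mean_r2(distant)

    def test_zero_switch_rate_copies_founders(self):
        cfg = small_config(mosaic_switch_rate=0.0, n_founder_haplotypes=4,
                          n_chromosomes=1, chromosome_labels=("13",))
        pool, _ = simulate_base_haplotypes(cfg, n_haplotypes=50)
        # with no switches every haplotype equals one of at most 4 founders
        assert len({h.tobytes() for h in pool}) <= 4

    def test_snp_map_positions_increase_within_chromosome(self):
        _, snp_map = simulate_base_haplotypes(small_config(), n_haplotypes=10)
        for _, grp in snp_map.groupby("chromosome", sort=False):
            assert (np.diff(grp["position"].to_numpy()) > 0).all()
            assert (np.diff(grp["genetic_position"].to_numpy()) > 0).all()

    def test_rejects_too_few_founders(self):
        with pytest.raises(ValueError, match="founder"):
            small_config(n_founder_haplotypes=1)


class TestEvolvePopulations:
    def test_population_sizes_and_labels(self, tiny_panel):
        labels, counts = np.unique(np.asarray(tiny_panel.population_labels,
                                              dtype=str), return_counts=True)
        got = dict(zip(labels, counts))
        assert got == {"HF": 120, "GWH": 50, "MRY": 60}

    def test_entries_are_allele_counts(self, tiny_panel):
        assert set(np.unique(tiny_panel.allele_counts)) <= {0, 1, 2}

    def test_drift_increases_frequency_divergence(self):
        """More Wright-Fisher generations, more allele-frequency spread."""
        base = small_config(seed=5, divergence_generations=0)
        drifted = small_config(seed=5, divergence_generations=40)
        pool, snp_map = simulate_base_haplotypes(base)

        def mean_abs_dfreq(cfg):
            panel = evolve_populations(pool, snp_map, cfg).panel
            f = [panel.allele_counts[panel.individuals_of(p)].mean(0) / 2
                 for p in panel.populations[:2]]
            return np.abs(f[0] - f[1]).mean()

        d0 = mean_abs_dfreq(base)
        d40 = mean_abs_dfreq(drifted)
        assert d40 > d0
        # with no drift the divergence is pure sampling noise
        assert d0 < 0.1

    def test_rejects_tiny_population(self):
        pool, snp_map = simulate_base_haplotypes(small_config())
        with pytest.raises(ValueError, match="at least 2"):
            evolve_populations(pool, snp_map,
                               small_config(n_individuals=(1, 20, 20)))

    def test_pedigree_parents_exist_in_same_population(self, tiny_data):
        ped = tiny_data.pedigree
        by_id = ped.set_index("individual_id")["population"]
        for _, row in ped[ped["generation"] == 1].iterrows():
            for parent in (row["sire_id"], row["dam_id"]):
                assert parent in by_id.index
                assert by_id[parent] == row["population"]

    def test_half_sib_families_in_large_population(self, tiny_data):
        ped = tiny_data.pedigree
        hf = ped[(ped["population"] == "HF") & (ped["generation"] == 1)]
        biggest_family = hf.groupby("sire_id").size().max()
        assert biggest_family >= 10  # sire-limited final generation


class TestMafFilter:
    def make_panel(self, counts):
        counts = np.asarray(counts, dtype=np.int8)
        n, m = counts.shape
        snp_map = pd.DataFrame({
            "snp_id": [f"s{j}" for j in range(m)], "chromosome": "1",
            "position": np.arange(1, m + 1),
            "genetic_position": np.linspace(0, 1, m),
        })
        return GenotypePanel(counts, [f"i{i}" for i in range(n)],
                             ["A"] * n, snp_map)

    def test_boundary_maf_is_removed(self):
        """A SNP at exactly the threshold frequency is deleted."""
        # 100 individuals, one allele copy -> MAF exactly 0.005
        counts = np.zeros((100, 2), dtype=np.int8)
        counts[0, 0] = 1       # MAF 0.005
        counts[:40, 1] = 1     # MAF 0.2
        out = apply_maf_filter(self.make_panel(counts), 0.005)
        assert list(out.snp_map["snp_id"]) == ["s1"]

    def test_monomorphic_removed_at_zero_threshold(self):
        counts = np.column_stack([np.zeros(20), np.ones(20)]).astype(np.int8)
        out = apply_maf_filter(self.make_panel(counts), 0.0)
        assert list(out.snp_map["snp_id"]) == ["s1"]

    def test_matches_brute_force_column_scan(self):
        rng = np.random.default_rng(3)
        counts = rng.integers(0, 3, size=(200, 50)).astype(np.int8)
        # brute force: per-column allele counting
        keep = []
        for j in range(50):
            freq = counts[:, j].sum() / (2 * 200)
            if min(freq, 1 - freq) > 0.05:
                keep.append(f"s{j}")
        out = apply_maf_filter(self.make_panel(counts), 0.05)
        assert list(out.snp_map["snp_id"]) == keep

    def test_idempotent(self, tiny_panel):
        once = apply_maf_filter(tiny_panel, 0.01)
        twice = apply_maf_filter(once, 0.01)
        assert once.n_snps == twice.n_snps
        np.testing.assert_array_equal(once.allele_counts, twice.allele_counts)

    def test_rejects_bad_threshold(self, tiny_panel):
        for bad in (-0.1, 0.5, 0.7):
            with pytest.raises(ValueError):
                apply_maf_filter(tiny_panel, bad)


class TestPlinkIO:
    def test_round_trip_identity(self, tiny_data, tmp_path):
        prefix = tmp_path / "panel"
        write_genotypes(tiny_data.panel, prefix, tiny_data.pedigree)
        panel, pedigree = read_genotypes(prefix)
        np.testing.assert_array_equal(panel.allele_counts,
                                      tiny_data.panel.allele_counts)
        assert list(panel.individual_ids) == list(tiny_data.panel.individual_ids)
        assert list(panel.population_labels) == list(tiny_data.panel.population_labels)
        pd.testing.assert_frame_equal(
            panel.snp_map.reset_index(drop=True),
            tiny_data.panel.snp_map.reset_index(drop=True),
            check_dtype=False)
        assert len(pedigree) == len(tiny_data.pedigree)

    def test_single_genotype_bed_bytes(self, tmp_path):
        """One individual, one SNP, count 2: payload decodes by hand."""
        snp_map = pd.DataFrame({"snp_id": ["s0"], "chromosome": ["13"],
                                "position": [1], "genetic_position": [0.0]})
        panel = GenotypePanel(np.array([[2]], dtype=np.int8), ["i0"],
                              ["GWH"], snp_map)
        prefix = tmp_path / "one"
        write_genotypes(panel, prefix)
        raw = (tmp_path / "one.bed").read_bytes()
        # magic 6c 1b, SNP-major flag 01, then one byte whose low 2 bits
        # are 00 = homozygous for the counted allele (count 2)
        assert raw[:3] == b"\x6c\x1b\x01"
        assert len(raw) == 4
        assert raw[3] & 0b11 == 0b00
        back, _ = read_genotypes(prefix)
        assert back.allele_counts[0, 0] == 2
        assert list(back.population_labels) == ["GWH"]

    def test_bad_magic_reports_offset(self, tiny_data, tmp_path):
        prefix = tmp_path / "bad"
        write_genotypes(tiny_data.panel, prefix)
        raw = bytearray((tmp_path / "bad.bed").read_bytes())
        raw[1] = 0x00
        (tmp_path / "bad.bed").write_bytes(bytes(raw))
        with pytest.raises(ValueError, match="byte offset 1"):
            read_genotypes(prefix)

    def test_truncated_payload_reports_offset(self, tiny_data, tmp_path):
        prefix = tmp_path / "trunc"
        write_genotypes(tiny_data.panel, prefix)
        raw = (tmp_path / "trunc.bed").read_bytes()
        (tmp_path / "trunc.bed").write_bytes(raw[:-5])
        with pytest.raises(ValueError, match="truncated"):
            read_genotypes(prefix)


class TestPanelStructure:
    def test_ld_decay_monotone_over_distance_bins(self, tiny_panel):
        """Mean r^2 per genetic-distance bin decreases (Spearman <= -0.8)."""
        panel = tiny_panel
        chrom = panel.snp_map["chromosome"].iloc[0]
        idx = np.flatnonzero((panel.snp_map["chromosome"] == chrom).to_numpy())
        rows = panel.individuals_of("HF")
        X = panel.allele_counts[np.ix_(rows, idx)].astype(float)
        gpos = panel.snp_map["genetic_position"].to_numpy()[idx]
        rng = np.random.default_rng(0)
        pairs = rng.integers(0, len(idx), size=(8000, 2))
        pairs = pairs[pairs[:, 0] != pairs[:, 1]]
        Xc = X - X.mean(0)
        sd = X.std(0)
        num = (Xc[:, pairs[:, 0]] * Xc[:, pairs[:, 1]]).mean(0)
        with np.errstate(invalid="ignore"):
            r2 = (num / (sd[pairs[:, 0]] * sd[pairs[:, 1]])) ** 2
        d = np.abs(gpos[pairs[:, 0]] - gpos[pairs[:, 1]])
        bins = np.array([0, 0.02, 0.05, 0.1, 0.2, 0.4, 1.0])
        bi = np.digitize(d, bins) - 1
        means = [np.nanmean(r2[bi == k]) for k in range(len(bins) - 1)]
        rho = stats.spearmanr(np.arange(len(means)), means).statistic
        assert rho <= -0.8

    @pytest.mark.parametrize("seed", [11, 22, 33])
    def test_within_relationships_vary_more_than_across(self, seed):
        """Var(G) over within-population pairs exceeds the across value,
        so M_e comes out larger across populations (3 seeds)."""
        from crosspred.greml import compute_grm
        data = simulate_panel(PopSimConfig(
            n_individuals=(60, 30, 30), within_pop_ne=(120, 60, 60),
            n_snps_per_chromosome=250, n_founder_haplotypes=10,
            divergence_generations=30, seed=seed))
        panel = data.panel
        G = compute_grm(panel.allele_counts).matrix
        a = panel.individuals_of(panel.populations[0])
        b = panel.individuals_of(panel.populations[1])
        iu = np.triu_indices(len(a), k=1)
        var_within = G[np.ix_(a, a)][iu].var()
        var_across = G[np.ix_(a, b)].ravel().var()
        assert var_within > var_across
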