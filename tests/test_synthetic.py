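"""Construction invariants and determinism of the planted-truth simulators."""

import dataclasses

import numpy as np
import pytest

from chromrisk import synthetic
from chromrisk.data_io import map_variants_to_intervals
from chromrisk.synthetic import SimulationSpec


def small_spec(**overrides):
    base = dict(seed=9, chrom_lengths={"chrA": 150_000, "chrB": 150_000},
                peaks_per_type=25, cells_per_type=20, n_variants=300,
                n_ld_blocks=40)
    base.update(overrides)
    return SimulationSpec(**base)


class TestGenome:
    def test_requested_lengths(self):
        spec = small_spec()
        genome = synthetic.generate_genome(spec)
        assert genome.lengths == spec.chrom_lengths

    def test_gc_one_gives_only_gc(self):
        genome = synthetic.generate_genome(small_spec(gc_fraction=1.0))
        assert set(genome.sequences["chrA"]) <= {"G", "C"}

    def test_same_seed_identical_different_seed_not(self):
        a = synthetic.generate_genome(small_spec())
        b = synthetic.generate_genome(small_spec())
        c = synthetic.generate_genome(small_spec(seed=10))
        assert a.sequences == b.sequences
        assert a.sequences != c.sequences

    def test_gc_fraction_validated(self):
        with pytest.raises(ValueError, match="gc_fraction"):
            small_spec(gc_fraction=1.2)


class TestPeaksAndMotifs:
    def test_every_type_has_requested_count_and_motifs_in_genome(self):
        spec = small_spec()
        genome = synthetic.generate_genome(spec)
        genome, peaksets, truth = synthetic.plant_peaks_and_motifs(genome, spec)
        for t, ps in peaksets.items():
            assert len(ps) == spec.peaks_per_type
        for _, row in truth[truth["owner"] != "shared"].iterrows():
            motif = spec.motifs[row["owner"]]
            start = int(row["motif_start"])
            assert genome.sequences[row["chrom"]][
                start:start + len(motif)] == motif
            assert row["start"] <= start and start + len(motif) <= row["end"]

    def test_peaks_disjoint_and_separated_by_peak_length(self):
        spec = small_spec()
        genome = synthetic.generate_genome(spec)
        _, _, truth = synthetic.plant_peaks_and_motifs(genome, spec)
        for chrom, sub in truth.sort_values("start").groupby("chrom"):
            gaps = sub["start"].to_numpy()[1:] - sub["end"].to_numpy()[:-1]
            assert (gaps >= spec.peak_length).all()

    def test_shared_fraction_one_makes_all_sets_equal(self):
        # all-shared leaves no room for private motif peaks
        with pytest.raises(ValueError, match="budget"):
            spec = small_spec(shared_fraction=1.0, lineage_gradient=0.0)
            genome = synthetic.generate_genome(spec)
            synthetic.plant_peaks_and_motifs(genome, spec)

    def test_capacity_error_when_genome_too_small(self):
        spec = small_spec(chrom_lengths={"chrA": 30_000, "chrB": 30_000},
                          peaks_per_type=200)
        genome = synthetic.generate_genome(spec)
        with pytest.raises(ValueError, match="too small"):
            synthetic.plant_peaks_and_motifs(genome, spec)

    def test_lineage_gradient_nested_ownership(self):
        spec = small_spec(lineage_gradient=0.6)
        genome = synthetic.generate_genome(spec)
        _, peaksets, truth = synthetic.plant_peaks_and_motifs(genome, spec)
        vuln = set(map(tuple, truth.loc[
            truth["owner"] == spec.vulnerable_type,
            ["chrom", "start"]].values))
        borrowed = []
        for t in spec.lineage[:-1]:
            keys = set(map(tuple, peaksets[t].df[["chrom", "start"]].values))
            borrowed.append(keys & vuln)
        # monotone nesting along the lineage
        assert borrowed[0] <= borrowed[1] <= borrowed[2]
        assert len(borrowed[0]) < len(borrowed[2])


class TestCellMatrix:
    def test_capture_one_noise_zero_reproduces_own_peaks(self):
        spec = small_spec(capture_rate=1.0, noise_rate=0.0)
        genome = synthetic.generate_genome(spec)
        _, peaksets, truth = synthetic.plant_peaks_and_motifs(genome, spec)
        matrix, cells = synthetic.simulate_cell_matrix(peaksets, spec)
        union = matrix.peaks.df
        key_to_col = {(c, s): i for i, (c, s) in
                      enumerate(zip(union["chrom"], union["start"]))}
        dense = matrix.counts.toarray()
        for t in spec.cell_types:
            own = sorted(key_to_col[(c, s)] for c, s in
                         zip(peaksets[t].df["chrom"], peaksets[t].df["start"]))
            rows = dense[(cells["cell_type"] == t).to_numpy()]
            assert (np.flatnonzero(rows[0]) == own).all()

    def test_capture_zero_noise_zero_all_zero(self):
        spec = small_spec(capture_rate=0.0, noise_rate=0.0)
        genome = synthetic.generate_genome(spec)
        _, peaksets, _ = synthetic.plant_peaks_and_motifs(genome, spec)
        matrix, _ = synthetic.simulate_cell_matrix(peaksets, spec)
        assert matrix.counts.nnz == 0

    def test_row_sums_match_binomial_expectation(self):
        # mean row sum = capture*own + noise*other within 3 binomial SDs
        spec = small_spec(peaks_per_type=50, cells_per_type=100,
                          capture_rate=0.8, noise_rate=0.05,
                          chrom_lengths={"chrA": 400_000, "chrB": 400_000},
                          lineage_gradient=0.0, shared_fraction=0.0)
        genome = synthetic.generate_genome(spec)
        _, peaksets, truth = synthetic.plant_peaks_and_motifs(genome, spec)
        matrix, cells = synthetic.simulate_cell_matrix(peaksets, spec)
        n_own = spec.peaks_per_type
        n_other = len(matrix.peaks) - n_own
        expected = 0.8 * n_own + 0.05 * n_other
        var = 0.8 * 0.2 * n_own + 0.05 * 0.95 * n_other
        n_cells = len(cells)
        row_sums = np.asarray(matrix.counts.sum(axis=1)).ravel()
        assert abs(row_sums.mean() - expected) < 3 * np.sqrt(var / n_cells)

    def test_pseudotime_follows_lineage_rank(self):
        spec = small_spec()
        genome = synthetic.generate_genome(spec)
        _, peaksets, _ = synthetic.plant_peaks_and_motifs(genome, spec)
        _, cells = synthetic.simulate_cell_matrix(peaksets, spec)
        for rank, t in enumerate(spec.lineage):
            pt = cells.loc[cells["cell_type"] == t, "pseudotime"]
            assert (pt >= rank).all() and (pt < rank + 1).all()

    def test_zero_cells_rejected(self):
        with pytest.raises(ValueError, match="[Zz]ero cells"):
            spec = small_spec(cells_per_type=0)
            genome = synthetic.generate_genome(spec)
            _, peaksets, _ = synthetic.plant_peaks_and_motifs(genome, spec)
            synthetic.simulate_cell_matrix(peaksets, spec)


@pytest.fixture(scope="module")
def gwas():
    spec = small_spec()
    genome = synthetic.generate_genome(spec)
    genome, peaksets, truth = synthetic.plant_peaks_and_motifs(genome, spec)
    variants = synthetic.simulate_gwas(genome, truth, spec)
    return spec, genome, peaksets, truth, variants


class TestGwas:
    def test_fraction_functional_zero_all_neutral(self):
        spec = small_spec(fraction_functional=0.0)
        genome = synthetic.generate_genome(spec)
        genome, _, truth = synthetic.plant_peaks_and_motifs(genome, spec)
        variants = synthetic.simulate_gwas(genome, truth, spec)
        assert (variants["is_functional"] == 0).all()

    def test_functional_variants_sit_on_motif_consensus(self, gwas):
        spec, genome, peaksets, truth, variants = gwas
        func = variants[variants["is_functional"] == 1]
        assert len(func) == round(spec.n_variants * spec.fraction_functional)
        motif = spec.motifs[spec.vulnerable_type]
        vuln = truth[truth["owner"] == spec.vulnerable_type]
        for _, v in func.iterrows():
            assert genome.base_at(v["chrom"], v["pos"]) == v["ref"]
            hit = vuln[(vuln["chrom"] == v["chrom"])
                       & (vuln["motif_start"] <= v["pos"] - 1)
                       & (v["pos"] - 1 < vuln["motif_start"] + len(motif))]
            assert len(hit) == 1
            offset = int(v["pos"] - 1 - hit["motif_start"].iloc[0])
            assert v["ref"] == motif[offset]      # ref = consensus
            assert v["alt"] != motif[offset]      # alt breaks the motif

    def test_planted_direction_matches_z_sign(self, gwas):
        _, _, _, _, variants = gwas
        func = variants[variants["is_functional"] == 1]
        assert ((func["z"] > 0) == (func["planted_direction"] == -1)).all()
        neutral = variants[variants["is_functional"] == 0]
        assert (neutral["planted_direction"] == 0).all()

    def test_neutral_variants_avoid_motifs(self, gwas):
        spec, _, _, truth, variants = gwas
        neutral = variants[variants["is_functional"] == 0]
        planted = truth[truth["motif_start"] >= 0]
        for _, row in planted.iterrows():
            motif_len = len(spec.motifs[row["owner"]])
            inside = ((neutral["chrom"] == row["chrom"])
                      & (neutral["pos"] - 1 >= row["motif_start"])
                      & (neutral["pos"] - 1 < row["motif_start"] + motif_len))
            assert not inside.any()

    def test_z_magnitudes_match_folded_normal_oracle(self):
        # functional |z| ~ |N(4,1)| ~= 4; neutral |z| ~ folded N(0,1),
        # mean sqrt(2/pi) ~= 0.798 (Monte Carlo oracle below)
        mc = np.random.default_rng(123)
        neutral_oracle = np.abs(mc.normal(size=200_000)).mean()
        assert abs(neutral_oracle - np.sqrt(2 / np.pi)) < 0.01
        spec = small_spec(n_variants=2000, fraction_functional=0.1,
                          peaks_per_type=40,
                          chrom_lengths={"chrA": 250_000, "chrB": 250_000})
        genome = synthetic.generate_genome(spec)
        genome, _, truth = synthetic.plant_peaks_and_motifs(genome, spec)
        v = synthetic.simulate_gwas(genome, truth, spec)
        func = np.abs(v.loc[v["is_functional"] == 1, "z"])
        neut = np.abs(v.loc[v["is_functional"] == 0, "z"])
        assert abs(func.mean() - 4.0) < 3 * func.std() / np.sqrt(len(func))
        assert abs(neut.mean() - neutral_oracle) < 3 * neut.std() / np.sqrt(len(neut))

    def test_pp_separates_functional(self, gwas):
        _, _, _, _, variants = gwas
        assert variants.loc[variants["is_functional"] == 1, "pp"].min() >= 0.5
        assert variants.loc[variants["is_functional"] == 0, "pp"].max() <= 0.1

    def test_error_when_functional_exceed_motif_positions(self):
        spec = small_spec(n_variants=5000, fraction_functional=0.5)
        genome = synthetic.generate_genome(spec)
        genome, _, truth = synthetic.plant_peaks_and_motifs(genome, spec)
        with pytest.raises(ValueError, match="motif positions"):
            synthetic.simulate_gwas(genome, truth, spec)


class TestDeterminism:
    def test_full_bundle_byte_identical_under_seed(self, tmp_path):
        spec = small_spec()
        d1, d2 = tmp_path / "a", tmp_path / "b"
        synthetic.write_bundle(synthetic.simulate_bundle(spec), d1)
        synthetic.write_bundle(synthetic.simulate_bundle(
            dataclasses.replace(spec)), d2)
        for p1 in sorted(d1.iterdir()):
            assert p1.read_bytes() == (d2 / p1.name).read_bytes(), p1.name


def test_promoter_intervals_strand_aware():
    import pandas as pd
    genes = pd.DataFrame({
        "gene_id": ["g1", "g2"], "chrom": ["chrA", "chrA"],
        "tss": [5000, 9000], "strand": ["+", "-"]})
    ivs = synthetic.promoter_intervals(genes)
    rows = ivs.df.values.tolist()
    assert rows[0] == ["chrA", 3999, 5100]   # [TSS-1000, TSS+100] on +
    assert rows[1] == ["chrA", 8899, 10000]  # mirrored on -
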