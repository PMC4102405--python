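import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from thermocurve.potentials import (
    FrequencyTable,
    build_thermal_datasets,
    corrected_ratio,
    count_descriptors,
    default_kernel,
    potential_from_counts,
    read_potentials,
    sequence_identity,
    smooth_bins,
    write_potentials,
)
from thermocurve.structures import distance_bin

from conftest import make_protein


class TestSequenceIdentity:
    @pytest.mark.parametrize("a, b, expected", [
        ("ACDE", "ACDE", 100.0),
        ("ACDE", "ACDF", 75.0),
        ("AAAA", "CCCC", 0.0),
    ])
    def test_examples(self, a, b, expected):
        assert sequence_identity(a, b) == pytest.approx(expected)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            sequence_identity("", "ACDE")


class TestBuildThermalDatasets:
    def _proteins(self, tms, seqs=None):
        out = []
        for k, tm in enumerate(tms):
            seq = (seqs[k] if seqs else
                   "".join("ACDEFHIKLMNPQRSTVWY"[(k * 7 + i * 3) % 19]
                           for i in range(12)))
            out.append(make_protein([(aa, (i * 4.0, k * 1.0, 0.0))
                                     for i, aa in enumerate(seq)],
                                    pid=f"p{k}", tm_exp=tm))
        return out

    def test_split_and_means(self):
        ds = build_thermal_datasets(self._proteins([40, 50, 80, 90]),
                                    tm_cutoff=70, identity_cap=100.0)
        assert ds.mean_tm("meso") == pytest.approx(45)
        assert ds.mean_tm("thermo") == pytest.approx(85)
        assert ds.mean_tm("all") == pytest.approx(65)

    def test_identical_pair_reduced(self):
        seqs = ["ACDEFHIKLMNP", "ACDEFHIKLMNP", "YWVTSRQPNMLK", "KLMNPQRSTVWY"]
        ps = self._proteins([40, 50, 80, 90], seqs)
        ds = build_thermal_datasets(ps, tm_cutoff=70, identity_cap=25)
        kept_meso = {p.id for p in ds.meso}
        assert len(kept_meso) == 1

    def test_environmental_temperature_augmentation(self):
        ps = self._proteins([40, 50, 80, 90])
        extra = make_protein([(aa, (i * 4.0, 9.0, 0.0)) for i, aa in
                              enumerate("WYVAHCDEFIKL")],
                             pid="env_only", t_env=75.0)
        ds = build_thermal_datasets(ps + [extra], tm_cutoff=70,
                                    tenv_to_tm=lambda t: t + 10.0)
        assert "env_only" in {p.id for p in ds.thermo}
        assert "env_only" in ds.estimated_ids
        assert ds.tm_values["env_only"] == pytest.approx(85.0)

    def test_unbalanced_rejected(self):
        with pytest.raises(ValueError, match="unbalanced"):
            build_thermal_datasets(self._proteins([40, 50, 55, 60]),
                                   tm_cutoff=70)

    def test_missing_tm_rejected(self):
        bad = make_protein([("A", (0, 0, 0))], pid="no_tm")
        with pytest.raises(ValueError, match="no experimental Tm"):
            build_thermal_datasets([bad], tm_cutoff=70)


class TestCountDescriptors:
    def test_separation_filter(self):
        p = make_protein([("A", (0, 0, 0)), ("L", (4, 0, 0)),
                          ("S", (0, 5, 0))])
        t = count_descriptors([p], "distance", min_separation=2)
        assert t.total == 1
        ((key, count),) = t.counts.items()
        assert key[0] == ("A", "S")

    def test_unordered_pair_pooling(self):
        p1 = make_protein([("A", (0, 0, 0)), ("G", (40, 0, 0)),
                          ("S", (4, 0, 0))], pid="p1")
        p2 = make_protein([("S", (0, 0, 0)), ("G", (40, 0, 0)),
                          ("A", (4, 0, 0))], pid="p2")
        t = count_descriptors([p1, p2], "distance", min_separation=2)
        assert t.counts[(("A", "S"), distance_bin(4.0))] == 2

    def test_matches_exhaustive_tally(self):
        rng = np.random.default_rng(11)
        aas = list("ACDEFHIKLV")
        coords = rng.uniform(0, 12, size=(10, 3))
        p = make_protein(list(zip(aas, coords)), pid="r")
        t = count_descriptors([p], "distance", min_separation=2)
        # independent brute-force tally
        expected: dict = {}
        for i in range(10):
            for j in range(i + 2, 10):
                d = math.dist(coords[i], coords[j])
                if d < 3.0:
                    b = 0
                elif d >= 8.0:
                    b = 26
                else:
                    b = 1 + int((d - 3.0) // 0.2)
                key = (tuple(sorted((aas[i], aas[j]))), b)
                expected[key] = expected.get(key, 0) + 1
        assert t.counts == expected
        assert t.total == sum(expected.values())

    def test_torsion_counts_skip_undefined(self):
        from thermocurve.synthetic import build_backbone
        from thermocurve.structures import ProteinStructure, Residue
        n, ca, c = build_backbone([-57.0] * 5, [-47.0] * 5)
        res = [Residue(index=i + 1, aa_type="A",
                       backbone_coords={"N": n[i], "CA": ca[i], "C": c[i]})
               for i in range(5)]
        p = ProteinStructure(id="h", chain="A", residues=res)
        t = count_descriptors([p], "torsion")
        # first residue lacks phi, last lacks psi -> 3 defined domains
        assert t.total == 3
        assert t.counts[("A", "A")] == 3

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            count_descriptors([], "distance")


class TestMarginalConsistency:
    @given(st.lists(st.tuples(st.integers(0, 3), st.integers(0, 5),
                              st.floats(0, 50)), min_size=1, max_size=30))
    @settings(max_examples=100, derandomize=True)
    def test_marginals_equal_row_column_sums(self, cells):
        counts: dict = {}
        for s, c, v in cells:
            counts[(f"s{s}", c)] = counts.get((f"s{s}", c), 0.0) + v
        t = FrequencyTable(kind="distance", counts=counts)
        assert t.total == pytest.approx(sum(counts.values()), abs=1e-9)
        for s in t.seq_marginals:
            row = sum(v for (ss, _), v in counts.items() if ss == s)
            assert t.seq_marginals[s] == pytest.approx(row, abs=1e-9)
        for c in t.struct_marginals:
            col = sum(v for (_, cc), v in counts.items() if cc == c)
            assert t.struct_marginals[c] == pytest.approx(col, abs=1e-9)


class TestSmoothBins:
    def test_interior_delta_spreads_and_conserves(self):
        v = np.zeros(25)
        v[12] = 100.0
        out = smooth_bins(v, default_kernel())
        assert out.sum() == pytest.approx(100.0, abs=1e-9)
        assert np.count_nonzero(out) == 5
        assert out[12] == pytest.approx(100 * 1.0 / 2.5)
        assert out[11] == out[13] == pytest.approx(100 * 0.5 / 2.5)

    def test_uniform_interior_unchanged(self):
        v = np.ones(25) * 7.0
        out = smooth_bins(v, default_kernel())
        # bins whose full neighbourhood is away from the edges are exact;
        # edge renormalisation perturbs the outermost four on each side
        np.testing.assert_allclose(out[4:-4], 7.0, atol=1e-12)

    @given(st.lists(st.floats(0, 100), min_size=5, max_size=30))
    @settings(max_examples=100, derandomize=True)
    def test_mass_conserved(self, vals):
        v = np.array(vals)
        out = smooth_bins(v, default_kernel())
        assert out.sum() == pytest.approx(v.sum(), abs=1e-9)

    @pytest.mark.parametrize("bad", [
        [0.5, 1.0, 0.5, 1.0, 0.5],  # increasing away from center
        [1.0, -0.5, 1.0],           # negative
        [1.0, 0.5],               # even length
    ])
    def test_bad_kernels_rejected(self, bad):
        with pytest.raises(ValueError):
            smooth_bins(np.ones(10), np.array(bad))


class TestCorrectedRatio:
    def test_unobserved_cell_gives_independence(self):
        assert corrected_ratio(0, None, 10.0) == 1.0

    def test_count_equal_sigma_is_midpoint(self):
        r = 3.7
        assert corrected_ratio(10.0, r, 10.0) == pytest.approx((1 + r) / 2)

    def test_large_count_limit(self):
        assert corrected_ratio(1e9 * 10, 2.0, 10.0) == pytest.approx(2.0, abs=1e-6)

    def test_invalid_sigma(self):
        with pytest.raises(ValueError):
            corrected_ratio(1.0, 1.0, 0.0)

    @given(st.floats(0.1, 1e5), st.floats(0.01, 100), st.floats(0.1, 1000))
    @settings(max_examples=200, derandomize=True)
    def test_between_one_and_observed(self, n, robs, sigma):
        out = corrected_ratio(n, robs, sigma)
        lo, hi = sorted((1.0, robs))
        assert lo <= out <= hi


class TestPotentialFromCounts:
    def test_independent_counts_give_zero_potential(self):
        # counts n(s,c) = n(s) n(c) / n exactly -> ratio 1 everywhere
        row = {"A": 40.0, "L": 60.0}
        col = {"X": 30.0, "Y": 50.0, "Z": 20.0}
        total = 100.0
        counts = {(s, c): row[s] * col[c] / total for s in row for c in col}
        pots = potential_from_counts(
            FrequencyTable(kind="torsion", counts=counts), sigma=20.0)
        for v in pots.values.values():
            assert v == pytest.approx(0.0, abs=1e-12)

    def test_small_table_matches_hand_computation(self):
        counts = {("A", "X"): 12.0, ("A", "Y"): 3.0,
                  ("L", "X"): 5.0, ("L", "Y"): 20.0}
        sigma = 20.0
        t = FrequencyTable(kind="torsion", counts=counts)
        pots = potential_from_counts(t, sigma=sigma)
        total = 40.0
        for (s, c), n_sc in counts.items():
            n_s = sum(v for (ss, _), v in counts.items() if ss == s)
            n_c = sum(v for (_, cc), v in counts.items() if cc == c)
            robs = n_sc * total / (n_s * n_c)
            expected = -math.log((sigma + n_sc * robs) / (sigma + n_sc))
            assert pots.energy(s, c) == pytest.approx(expected, abs=1e-12)

    def test_correction_vanishes_at_large_counts(self):
        counts = {("A", "X"): 12.0, ("A", "Y"): 3.0,
                  ("L", "X"): 5.0, ("L", "Y"): 20.0}
        big = {k: v * 1e9 for k, v in counts.items()}
        pots = potential_from_counts(
            FrequencyTable(kind="torsion", counts=big), sigma=20.0)
        total = 40.0
        for (s, c), n_sc in counts.items():
            n_s = sum(v for (ss, _), v in counts.items() if ss == s)
            n_c = sum(v for (_, cc), v in counts.items() if cc == c)
            robs = n_sc * total / (n_s * n_c)
            assert pots.energy(s, c) == pytest.approx(-math.log(robs),
                                                      abs=1e-5)

    def test_correction_shrinks_magnitude_cellwise(self):
        rng = np.random.default_rng(3)
        counts = {(f"s{i}", c): float(rng.integers(0, 30))
                  for i in range(4) for c in range(1, 26)}
        counts = {k: v for k, v in counts.items() if v > 0}
        t = FrequencyTable(kind="distance", counts=counts)
        for sigma in (1.0, 10.0, 100.0):
            pots = potential_from_counts(t, sigma=sigma)
            smoothed = t.smoothed(default_kernel())
            for (s, c), v in pots.values.items():
                n_sc = smoothed.counts.get((s, c), 0.0)
                n_s = smoothed.seq_marginals[s]
                n_c = smoothed.struct_marginals[c]
                robs = n_sc * smoothed.total / (n_s * n_c)
                uncorrected = -math.log(robs) if n_sc > 0 else 0.0
                assert abs(v) <= abs(uncorrected) + 1e-12

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            potential_from_counts(FrequencyTable(kind="torsion", counts={}))


class TestPotentialIO:
    def test_round_trip(self, tmp_path):
        counts = {(("A", "L"), 5): 10.0, (("A", "S"), 12): 4.0}
        pots = potential_from_counts(
            FrequencyTable(kind="distance", counts=counts, dataset_tag="meso"),
            sigma=10.0, dataset_mean_tm=48.5)
        path = tmp_path / "meso_distance.tsv"
        write_potentials(pots, path)
        back = read_potentials(path)
        assert back.kind == "distance"
        assert back.dataset_mean_tm == pytest.approx(48.5)
        assert back.dataset_tag == "meso"
        assert set(back.values) == set(pots.values)
        for k, v in pots.values.items():
            assert back.values[k] == pytest.approx(v, rel=1e-10)


class TestPlantedSignal:
    def test_enriched_cell_sign(self):
        from thermocurve.synthetic import (PlantedContactSpec,
                                           enriched_cell,
                                           generate_toy_structures)
        spec = PlantedContactSpec(odds_factor=4.0, n_structures=200, seed=0)
        meso, thermo, _ = generate_toy_structures(spec)
        cell = enriched_cell(spec)
        dm = potential_from_counts(
            count_descriptors(meso, "distance", dataset_tag="meso"))
        dt = potential_from_counts(
            count_descriptors(thermo, "distance", dataset_tag="thermo"))
        diff = dt.energy(*cell) - dm.energy(*cell)
        # enrichment in the thermo set lowers its energy for that cell
        assert diff < 0
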