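"""HDX-MS uptake normalization, site aggregation, alignment, correlation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thermosol import simulate as sim
from thermosol.hdx import (
    DeltaProfile,
    SiteAlignment,
    SiteProfile,
    delta_profile,
    domain_summary,
    element_summary,
    ortholog_site_correlation,
    pairwise_align,
    percent_uptake,
    site_profile,
)


def _profile_pair(peptides, seqs, state="monomer"):
    p1 = site_profile(
        peptides[(peptides.protein == "ortholog1") & (peptides.state == state)],
        seqs["ortholog1"],
    )
    p2 = site_profile(
        peptides[(peptides.protein == "ortholog2") & (peptides.state == state)],
        seqs["ortholog2"],
    )
    return p1, p2


class TestPercentUptake:
    @pytest.mark.parametrize(
        "mass_t,expected", [(1010.0, 100.0), (1000.0, 0.0), (1005.0, 50.0)]
    )
    def test_endpoints_and_midpoint(self, mass_t, expected):
        assert percent_uptake(mass_t, 1000.0, 1010.0) == pytest.approx(expected)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(
        shift=st.floats(-500, 500),
        frac=st.floats(0, 1),
    )
    def test_affine_invariance(self, shift, frac):
        # adding a constant to all three masses leaves %D unchanged
        undeut, sat = 1000.0, 1012.0
        mass_t = undeut + frac * (sat - undeut)
        a = percent_uptake(mass_t, undeut, sat)
        b = percent_uptake(mass_t + shift, undeut + shift, sat + shift)
        assert a == pytest.approx(b, abs=1e-9)

    def test_negative_uptake_flagged(self):
        with pytest.raises(ValueError, match="below undeuterated"):
            percent_uptake(998.0, 1000.0, 1010.0)

    def test_saturated_must_exceed_undeuterated(self):
        with pytest.raises(ValueError, match="exceed"):
            percent_uptake(1005.0, 1000.0, 1000.0)


class TestSiteProfile:
    SEQ = "A" * 30  # proline-free so coverage rules are easy to reason about

    @staticmethod
    def _pep(start, end, pct, state="monomer"):
        return {
            "protein": "prot",
            "state": state,
            "start": start,
            "end": end,
            "sequence": "A" * (end - start + 1),
            "timepoint_s": 100.0,
            "percent_d": pct,
        }

    def test_single_peptide_excludes_first_residue(self):
        prof = site_profile(pd.DataFrame([self._pep(10, 20, 40.0)]), self.SEQ)
        assert np.isnan(prof.values[9])  # residue 10, the peptide's N-terminus
        np.testing.assert_allclose(prof.values[10:20], 40.0)
        assert np.isnan(prof.values[0])

    def test_overlap_is_unweighted_mean(self):
        peps = pd.DataFrame([self._pep(1, 15, 40.0), self._pep(10, 25, 60.0)])
        prof = site_profile(peps, self.SEQ)
        np.testing.assert_allclose(prof.values[10:15], 50.0)  # residues 11-15
        np.testing.assert_allclose(prof.values[1:9], 40.0)

    def test_prolines_excluded_from_coverage(self):
        seq = "AAAAAPAAAA"
        prof = site_profile(pd.DataFrame([self._pep(1, 10, 30.0)]), seq)
        assert np.isnan(prof.values[5])  # the proline
        assert prof.values[4] == pytest.approx(30.0)

    def test_span_outside_sequence_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            site_profile(pd.DataFrame([self._pep(25, 40, 10.0)]), self.SEQ)

    def test_mixed_states_rejected(self):
        peps = pd.DataFrame(
            [self._pep(1, 10, 40.0), self._pep(1, 10, 50.0, state="condensate")]
        )
        with pytest.raises(ValueError, match="single state"):
            site_profile(peps, self.SEQ)

    def test_tiled_profile_tracks_truth(self, sine_profile):
        peps, seqs, truth = sim.simulate_hdx(
            {"monomer": sine_profile}, noise_sd=0.0, n_orthologs=1, seed=3
        )
        prof = site_profile(
            peps[peps.protein == "ortholog1"], seqs["ortholog1"]
        )
        t = 100.0 * truth[("ortholog1", "monomer")]
        ok = prof.coverage
        from scipy.stats import spearmanr

        rho = spearmanr(prof.values[ok], t[ok]).statistic
        assert rho > 0.95


class TestDeltaProfile:
    def test_identical_profiles_zero(self, sine_profile):
        vals = 100.0 * sine_profile
        a = SiteProfile("p", "condensate", 100.0, vals)
        b = SiteProfile("p", "monomer", 100.0, vals.copy())
        d = delta_profile(a, b)
        np.testing.assert_allclose(d.values, 0.0)

    def test_uniform_shift(self):
        mono = SiteProfile("p", "monomer", 100.0, np.full(50, 40.0))
        cond = SiteProfile("p", "condensate", 100.0, np.full(50, 50.0))
        np.testing.assert_allclose(delta_profile(cond, mono).values, 10.0)

    def test_antisymmetric_under_state_swap(self, sine_profile):
        a = SiteProfile("p", "condensate", 100.0, 100 * sine_profile)
        b = SiteProfile("p", "monomer", 100.0, 100 * sine_profile[::-1].copy())
        np.testing.assert_allclose(
            delta_profile(a, b).values, -delta_profile(b, a).values
        )

    def test_missing_propagates(self):
        va = np.array([10.0, np.nan, 30.0])
        vb = np.array([5.0, 20.0, np.nan])
        d = delta_profile(
            SiteProfile("p", "condensate", 100.0, va),
            SiteProfile("p", "monomer", 100.0, vb),
        )
        assert d.values[0] == pytest.approx(5.0)
        assert np.isnan(d.values[1]) and np.isnan(d.values[2])

    def test_mismatched_protein_rejected(self):
        a = SiteProfile("p1", "condensate", 100.0, np.zeros(5))
        b = SiteProfile("p2", "monomer", 100.0, np.zeros(5))
        with pytest.raises(ValueError, match="different proteins"):
            delta_profile(a, b)

    def test_protected_block_localized(self, sine_profile):
        cond = np.clip(sine_profile - 0.3 * (np.arange(300) // 100 == 1), 0, 1)
        peps, seqs, _ = sim.simulate_hdx(
            {"monomer": sine_profile, "condensate": cond},
            noise_sd=0.0,
            n_orthologs=1,
            seed=4,
        )
        sub = peps[peps.protein == "ortholog1"]
        mono = site_profile(sub[sub.state == "monomer"], seqs["ortholog1"])
        cnd = site_profile(sub[sub.state == "condensate"], seqs["ortholog1"])
        d = delta_profile(cnd, mono)
        # strongly negative inside the protected block, near zero outside
        # (tiling smears the block edges by up to a peptide length)
        inside = np.nanmean(d.values[115:185])
        outside = np.nanmean(np.concatenate([d.values[:85], d.values[215:]]))
        assert inside < -25.0
        assert abs(outside) < 2.0


class TestPairwiseAlign:
    def test_identical_sequences_identity_mapping(self):
        seq = "MKTAYIAKQRQISFVKSHFSRQ"
        aln = pairwise_align(seq, seq)
        assert aln.pairs == [(i, i) for i in range(1, len(seq) + 1)]

    def test_internal_deletion_single_gap_block(self):
        a = "MKTAYIAKQRQISFVKSHFSRQ"
        b = a[:10] + a[14:]  # delete 4 residues
        aln = pairwise_align(a, b)
        # mapping resumes with a +4 offset after the gap
        offsets = sorted({i - j for i, j in aln.pairs})
        assert offsets == [0, 4]

    def test_score_matches_dp_oracle(self):
        # independent Needleman-Wunsch with affine gaps (Gotoh), same scoring
        from Bio.Align import substitution_matrices

        blosum = substitution_matrices.load("BLOSUM62")
        rng = np.random.default_rng(0)
        aas = "ACDEFGHIKLMNPQRSTVWY"
        for _ in range(3):
            a = "".join(rng.choice(list(aas), 20))
            b = "".join(rng.choice(list(aas), 20))
            aln = pairwise_align(a, b)
            assert aln.score == pytest.approx(
                _gotoh_score(a, b, blosum, -11.0, -1.0)
            )

    def test_non_amino_acid_rejected(self):
        with pytest.raises(ValueError, match="non-amino-acid"):
            pairwise_align("MKTA1", "MKTA")

    def test_alignment_indices_strictly_increasing(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            SiteAlignment("a", "b", pairs=[(1, 2), (1, 3)])


def _gotoh_score(a, b, matrix, gap_open, gap_extend):
    """Affine-gap global alignment score by straightforward DP."""
    neg = float("-inf")
    n, m = len(a), len(b)
    M = np.full((n + 1, m + 1), neg)
    X = np.full((n + 1, m + 1), neg)  # gap in b (insertion in a)
    Y = np.full((n + 1, m + 1), neg)  # gap in a
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = gap_open + (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0, j] = gap_open + (j - 1) * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = matrix[a[i - 1], b[j - 1]]
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] + gap_open, X[i - 1, j] + gap_extend)
            Y[i, j] = max(M[i, j - 1] + gap_open, Y[i, j - 1] + gap_extend)
    return max(M[n, m], X[n, m], Y[n, m])


class TestOrthologCorrelation:
    def test_self_correlation_is_one(self, sine_profile):
        peps, seqs, _ = sim.simulate_hdx(
            {"monomer": sine_profile}, noise_sd=0.0, n_orthologs=1, seed=5
        )
        prof = site_profile(peps[peps.protein == "ortholog1"], seqs["ortholog1"])
        aln = pairwise_align(seqs["ortholog1"], seqs["ortholog1"])
        r, _ = ortholog_site_correlation(prof, prof, aln, n_shuffles=10, seed=0)
        assert r == pytest.approx(1.0)

    def test_shuffle_null_centred_near_zero(self, sine_profile):
        peps, seqs, _ = sim.simulate_hdx(
            {"monomer": sine_profile}, noise_sd=0.0, n_orthologs=1, seed=6
        )
        prof = site_profile(peps[peps.protein == "ortholog1"], seqs["ortholog1"])
        aln = pairwise_align(seqs["ortholog1"], seqs["ortholog1"])
        _, null = ortholog_site_correlation(prof, prof, aln, n_shuffles=500, seed=1)
        assert abs(null.mean()) < 0.1

    def test_null_reproducible_under_seed(self, sine_profile):
        peps, seqs, _ = sim.simulate_hdx(
            {"monomer": sine_profile}, noise_sd=0.0, n_orthologs=1, seed=7
        )
        prof = site_profile(peps[peps.protein == "ortholog1"], seqs["ortholog1"])
        aln = pairwise_align(seqs["ortholog1"], seqs["ortholog1"])
        _, n1 = ortholog_site_correlation(prof, prof, aln, n_shuffles=50, seed=2)
        _, n2 = ortholog_site_correlation(prof, prof, aln, n_shuffles=50, seed=2)
        np.testing.assert_array_equal(n1, n2)

    def test_diverged_orthologs_recover_shared_profile(self, sine_profile):
        peps, seqs, _ = sim.simulate_hdx(
            {"monomer": sine_profile},
            mutation_rate=0.1,
            n_orthologs=2,
            noise_sd=3.0,
            seed=8,
        )
        p1, p2 = _profile_pair(peps, seqs)
        aln = pairwise_align(seqs["ortholog1"], seqs["ortholog2"])
        r, null = ortholog_site_correlation(p1, p2, aln, n_shuffles=500, seed=3)
        assert r > 0.9
        assert r > np.percentile(null, 97.5)

    def test_insufficient_overlap_rejected(self):
        a = SiteProfile("a", "monomer", 100.0, np.arange(10.0))
        aln = SiteAlignment("a", "a", pairs=[(i, i) for i in range(1, 11)])
        with pytest.raises(ValueError, match="covered aligned columns"):
            ortholog_site_correlation(a, a, aln, n_shuffles=5, seed=0)


class TestElementAndDomainSummaries:
    def test_programmed_protection_ordering(self):
        # loops exchange fastest, then helices, then strands
        rng = np.random.default_rng(9)
        labels = np.array(["loop", "helix", "strand"])[rng.integers(0, 3, 300)]
        base = {"loop": 0.8, "helix": 0.5, "strand": 0.2}
        profile = np.clip(
            [base[l] + 0.05 * rng.standard_normal() for l in labels], 0, 1
        )
        peps, seqs, _ = sim.simulate_hdx(
            {"monomer": np.asarray(profile)}, noise_sd=0.0, n_orthologs=1, seed=10
        )
        prof = site_profile(peps[peps.protein == "ortholog1"], seqs["ortholog1"])
        summ = element_summary(prof, labels)
        assert (
            summ.loc["loop", "median"]
            > summ.loc["helix", "median"]
            > summ.loc["strand", "median"]
        )

    def test_uniform_profile_identical_medians(self):
        prof = SiteProfile("p", "monomer", 100.0, np.full(90, 42.0))
        labels = ["loop"] * 30 + ["helix"] * 30 + ["strand"] * 30
        summ = element_summary(prof, labels)
        assert summ["median"].nunique() == 1

    def test_single_element_equals_whole_profile_summary(self, sine_profile):
        prof = SiteProfile("p", "monomer", 100.0, 100 * sine_profile)
        summ = element_summary(prof, ["loop"] * 300)
        assert summ.loc["loop", "median"] == pytest.approx(
            np.median(100 * sine_profile)
        )

    def test_unknown_label_rejected(self):
        prof = SiteProfile("p", "monomer", 100.0, np.zeros(3))
        with pytest.raises(ValueError, match="unknown element"):
            element_summary(prof, ["loop", "sheet", "helix"])

    def test_constant_delta_domain_means(self):
        d = DeltaProfile("p", 100.0, np.full(100, 5.0))
        summ = domain_summary(d, {"RRM1": (1, 40), "Pdomain": (41, 100)})
        assert summ["mean"].tolist() == [5.0, 5.0]
        assert summ["se"].tolist() == [0.0, 0.0]

    def test_unique_protected_domain(self):
        vals = np.full(100, 5.0)
        vals[60:80] = -10.0
        d = DeltaProfile("p", 100.0, vals)
        summ = domain_summary(
            d, {"RRM1": (1, 60), "P": (61, 80), "CTD": (81, 100)}
        )
        assert summ.loc["P", "mean"] < 0
        assert (summ.drop("P")["mean"] > 0).all()

    def test_empty_domain_coverage_rejected(self):
        d = DeltaProfile("p", 100.0, np.full(100, np.nan))
        with pytest.raises(ValueError, match="no covered"):
            domain_summary(d, {"RRM1": (1, 50)})
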