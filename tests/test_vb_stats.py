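"""Tube-aware Vbeta frequencies, diversity, and expansion calls.

The brute-force oracle counts events row by row, independently of the
vectorized profile construction it checks.
"""

import numpy as np
import pandas as pd
import pytest

from vbflow import (
    GroundTruthManifest,
    PopulationSpec,
    generate_panel_design,
    simulate_sample,
)
from vbflow.panel import VB_NEGATIVE
from vbflow.synthetic import _phenotype, reference_vb_distribution
from vbflow.vb_stats import (
    ExpansionCall,
    call_expansions,
    expansion_kinetics,
    inverse_simpson,
    vb_profile,
)


def make_meta(panel, counts: dict[str, dict[str, int]]) -> pd.DataFrame:
    """Event metadata from per-tube {label: n} counts."""
    rows = []
    for tube_id, labels in counts.items():
        for label, n in labels.items():
            rows += [{"tube_id": tube_id, "vb_label": label}] * n
    return pd.DataFrame(rows)


def brute_force_profile(meta: pd.DataFrame, panel) -> dict[str, dict]:
    """Independent row-by-row event counter."""
    out = {}
    for fam in panel.families:
        tube = panel.tube_of(fam)
        n_pos = n_tube = 0
        for _, row in meta.iterrows():
            if row["vb_label"] == fam:
                n_pos += 1
            if row["tube_id"] == tube:
                n_tube += 1
        out[fam] = {
            "n_vb_pos": n_pos,
            "n_tube_scope": n_tube,
            "within": n_pos / len(meta),
            "tube_rel": n_pos / n_tube if n_tube else None,
        }
    return out


class TestVbProfile:
    def test_monoclonal_cluster_hits_pooling_bound(self, panel):
        """A fully monoclonal cluster over 8 equal tubes: within-cluster
        frequency is exactly 1/8 = 12.5%, tube-relative 100%."""
        fam = "Vb13.2"
        home = panel.tube_of(fam)
        counts = {
            t.tube_id: ({fam: 100} if t.tube_id == home else {VB_NEGATIVE: 100})
            for t in panel.tubes
        }
        prof = vb_profile(make_meta(panel, counts), panel, scope="clone")
        assert prof.table.loc[fam, "within_cluster_freq"] == 0.125
        assert prof.table.loc[fam, "tube_relative_freq"] == 1.0
        assert prof.dominant_family == fam

    def test_matches_brute_force_counter(self, panel):
        rng = np.random.default_rng(2)
        counts = {}
        for t in panel.tubes:
            labels = list(t.vb_families) + [VB_NEGATIVE]
            counts[t.tube_id] = {
                lab: int(rng.integers(0, 30)) for lab in labels
            }
            counts[t.tube_id][VB_NEGATIVE] += 1  # keep tubes nonempty
        meta = make_meta(panel, counts)
        prof = vb_profile(meta, panel, scope="x")
        oracle = brute_force_profile(meta, panel)
        for fam in panel.families:
            assert prof.table.loc[fam, "n_vb_pos"] == oracle[fam]["n_vb_pos"]
            assert prof.table.loc[fam, "within_cluster_freq"] == pytest.approx(
                oracle[fam]["within"]
            )
            assert prof.table.loc[fam, "tube_relative_freq"] == pytest.approx(
                oracle[fam]["tube_rel"]
            )

    def test_times_eight_identity_under_balanced_tubes(self, panel):
        """Within-cluster 10% under 8 balanced tubes = 80% tube-relative."""
        fam = panel.families[0]
        home = panel.tube_of(fam)
        counts = {
            t.tube_id: (
                {fam: 80, VB_NEGATIVE: 20}
                if t.tube_id == home
                else {VB_NEGATIVE: 100}
            )
            for t in panel.tubes
        }
        prof = vb_profile(make_meta(panel, counts), panel, scope="c")
        assert prof.table.loc[fam, "within_cluster_freq"] == pytest.approx(0.10)
        assert prof.table.loc[fam, "tube_relative_freq"] == pytest.approx(0.80)

    def test_zero_vb_cluster_reports_undetected(self, panel):
        counts = {t.tube_id: {VB_NEGATIVE: 50} for t in panel.tubes}
        prof = vb_profile(make_meta(panel, counts), panel, scope="c")
        assert prof.n_vb_pos_total == 0
        assert (prof.table["within_cluster_freq"] == 0).all()
        assert prof.dominant_family == "undetected"
        assert np.isnan(inverse_simpson(prof).inverse_simpson)

    def test_empty_tube_families_missing_not_zero(self, panel):
        counts = {
            t.tube_id: {VB_NEGATIVE: 50}
            for t in panel.tubes
            if t.tube_id != "tube3"
        }
        counts[panel.tubes[0].tube_id][panel.tubes[0].vb_families[0]] = 10
        prof = vb_profile(make_meta(panel, counts), panel, scope="c")
        for fam in panel.tube("tube3").vb_families:
            assert np.isnan(prof.table.loc[fam, "tube_relative_freq"])
        detected = prof.table["tube_relative_freq"].notna().sum()
        assert detected == 21  # 24 minus the empty tube's three

    def test_pooling_bound_property_exhaustive(self, panel):
        """within_cluster_freq <= tube's share of cluster events, with
        equality iff every event of that tube is positive for the family."""
        rng = np.random.default_rng(5)
        for _ in range(20):
            counts = {}
            for t in panel.tubes[:4]:
                n_pos = int(rng.integers(0, 10))
                n_neg = int(rng.integers(0, 10))
                if n_pos + n_neg == 0:
                    n_neg = 1
                counts[t.tube_id] = {
                    t.vb_families[0]: n_pos, VB_NEGATIVE: n_neg
                }
            meta = make_meta(panel, counts)
            prof = vb_profile(meta, panel, scope="c")
            n_total = len(meta)
            for t in panel.tubes[:4]:
                fam = t.vb_families[0]
                tube_share = (meta["tube_id"] == t.tube_id).sum() / n_total
                w = prof.table.loc[fam, "within_cluster_freq"]
                assert w <= tube_share + 1e-12
                all_pos = counts[t.tube_id][VB_NEGATIVE] == 0
                assert (abs(w - tube_share) < 1e-12) == all_pos


class TestInverseSimpson:
    def _uniform_profile(self, panel):
        counts = {
            t.tube_id: {f: 4 for f in t.vb_families} | {VB_NEGATIVE: 88}
            for t in panel.tubes
        }
        return vb_profile(make_meta(panel, counts), panel, scope="u")

    def test_uniform_24_families_gives_24(self, panel):
        div = inverse_simpson(self._uniform_profile(panel))
        assert div.inverse_simpson == pytest.approx(24.0, abs=1e-12)
        assert div.n_vb_pos_total == 96

    def test_monoclonal_gives_1(self, panel):
        fam = panel.families[5]
        counts = {panel.tube_of(fam): {fam: 30, VB_NEGATIVE: 10}}
        div = inverse_simpson(vb_profile(make_meta(panel, counts), panel, "m"))
        assert div.inverse_simpson == pytest.approx(1.0, abs=1e-12)

    def test_hand_computed_vector(self, panel):
        # p = (0.5, 0.25, 0.25): D = 1 / (0.25 + 0.0625 + 0.0625) = 8/3
        t = panel.tubes[0]
        counts = {
            t.tube_id: {
                t.vb_families[0]: 50,
                t.vb_families[1]: 25,
                t.vb_families[2]: 25,
            }
        }
        div = inverse_simpson(vb_profile(make_meta(panel, counts), panel, "h"))
        assert div.inverse_simpson == pytest.approx(8.0 / 3.0, abs=1e-12)

    def test_against_scikit_bio_oracle(self, panel):
        from skbio.diversity.alpha import enspie

        rng = np.random.default_rng(3)
        t = panel.tubes[0]
        raw = rng.integers(1, 50, size=3)
        counts = {t.tube_id: dict(zip(t.vb_families, map(int, raw)))}
        div = inverse_simpson(vb_profile(make_meta(panel, counts), panel, "r"))
        assert div.inverse_simpson == pytest.approx(enspie(raw), rel=1e-12)

    def test_bounds_and_majorization(self, panel):
        """1 <= D <= detected families; concentrating mass lowers D."""
        rng = np.random.default_rng(8)
        t = panel.tubes[0]
        prev = None
        for extra in (0, 20, 60, 200):
            counts = {
                t.tube_id: {
                    t.vb_families[0]: 10 + extra,
                    t.vb_families[1]: 10,
                    t.vb_families[2]: 10,
                }
            }
            d = inverse_simpson(
                vb_profile(make_meta(panel, counts), panel, "m")
            ).inverse_simpson
            assert 1.0 <= d <= 3.0 + 1e-12
            if prev is not None:
                assert d < prev
            prev = d
        del rng


def _profile_from_freqs(panel, freqs: np.ndarray, n_per_tube: int = 1000,
                        scope="c", rng=None):
    """Profile whose per-family counts are draws (or exact) at given
    tube-relative frequencies."""
    counts = {}
    fam_freq = dict(zip(panel.families, freqs))
    for t in panel.tubes:
        c = {}
        used = 0
        for fam in t.vb_families:
            if rng is None:
                n = int(round(fam_freq[fam] * n_per_tube))
            else:
                n = int(rng.binomial(n_per_tube, fam_freq[fam]))
            c[fam] = n
            used += n
        c[VB_NEGATIVE] = max(n_per_tube - used, 0)
        counts[t.tube_id] = c
    return vb_profile(make_meta(panel, counts), panel, scope=scope)


@pytest.fixture(scope="module")
def small_panel():
    return generate_panel_design()


class TestCallExpansions:
    def _base_freqs(self, panel):
        d = reference_vb_distribution(panel.families)
        return np.array([d[f] for f in panel.families])

    def test_planted_clonal_cluster_is_the_only_flag(self, small_panel):
        panel = small_panel
        rng = np.random.default_rng(11)
        base = self._base_freqs(panel)
        profiles = {
            k: _profile_from_freqs(panel, base, rng=rng, scope=f"c{k}")
            for k in range(5)
        }
        clonal = np.zeros(24)
        clonal[7] = 0.9
        profiles[5] = _profile_from_freqs(panel, clonal, scope="c5")
        ref = _profile_from_freqs(panel, base, rng=rng, scope="naive")
        calls = call_expansions(profiles, ref)
        assert len(calls) == 1
        assert calls[0].clusters == (5,)
        assert calls[0].dominant_family == panel.families[7]
        assert calls[0].dominance == pytest.approx(0.9)

    def test_null_clusters_from_naive_distribution_not_flagged(
        self, small_panel
    ):
        panel = small_panel
        rng = np.random.default_rng(12)
        base = self._base_freqs(panel)
        profiles = {
            k: _profile_from_freqs(panel, base, n_per_tube=2000, rng=rng)
            for k in range(6)
        }
        ref = _profile_from_freqs(panel, base, n_per_tube=2000, rng=rng)
        assert call_expansions(profiles, ref) == []

    def test_naive_reference_never_flags_itself(self, small_panel):
        panel = small_panel
        base = self._base_freqs(panel)
        ref = _profile_from_freqs(panel, base, scope="naive")
        self_copy = {0: _profile_from_freqs(panel, base, scope="naive2")}
        assert call_expansions(self_copy, ref) == []

    def test_single_cluster_falls_back_to_dominance_rule(self, small_panel):
        panel = small_panel
        clonal = np.zeros(24)
        clonal[0] = 0.8
        profiles = {0: _profile_from_freqs(panel, clonal)}
        ref = _profile_from_freqs(panel, self._base_freqs(panel))
        calls = call_expansions(profiles, ref)
        assert len(calls) == 1 and calls[0].dominance > 0.5

    def test_flagged_clusters_sharing_family_merge(self, small_panel):
        panel = small_panel
        clonal = np.zeros(24)
        clonal[3] = 0.9
        profiles = {
            0: _profile_from_freqs(panel, clonal, scope="a"),
            1: _profile_from_freqs(panel, clonal, scope="b"),
            2: _profile_from_freqs(panel, self._base_freqs(panel), scope="c"),
        }
        ref = _profile_from_freqs(panel, self._base_freqs(panel))
        calls = call_expansions(profiles, ref)
        assert len(calls) == 1
        assert set(calls[0].clusters) == {0, 1}


class TestKinetics:
    def _call(self, fam, freq, tp):
        return ExpansionCall(
            clusters=(0,), dominant_family=fam, dominance=0.9,
            fingerprint=("TIGIT+", "PD-1-", "CD45RA-"),
            total_frequency=freq, timepoint=tp,
        )

    def test_trajectory_recovered(self):
        calls = {
            "t1": [self._call("Vb12", 0.30, "t1")],
            "t2": [self._call("Vb12", 0.30, "t2")],
            "t3": [self._call("Vb12", 0.05, "t3")],
        }
        kin = expansion_kinetics(calls)
        assert len(kin) == 1
        assert list(kin[["t1", "t2", "t3"]].iloc[0]) == [0.30, 0.30, 0.05]

    def test_absent_timepoint_is_nd(self, tmp_path):
        from vbflow.vb_stats import kinetics_to_tsv

        calls = {
            "t1": [],
            "t2": [self._call("Vb8", 0.2, "t2")],
        }
        kin = expansion_kinetics(calls)
        assert np.isnan(kin["t1"].iloc[0])
        path = tmp_path / "kin.tsv"
        kinetics_to_tsv(kin, path)
        assert "ND" in path.read_text()

    def test_single_timepoint_degenerates_to_call_list(self):
        calls = {"only": [self._call("Vb2", 0.4, "only")]}
        kin = expansion_kinetics(calls)
        assert list(kin.columns) == ["dominant_family", "fingerprint", "only"]
        assert kin["only"].iloc[0] == 0.4

    def test_fingerprint_disambiguates_shared_family(self):
        """Two expansions of one family: matched by phenotype fingerprint."""
        a1 = ExpansionCall((0,), "Vb22", 0.9, ("TIGIT-", "PD-1+", "CD45RA-"),
                           total_frequency=0.10, timepoint="t1")
        a2 = ExpansionCall((1,), "Vb22", 0.8, ("TIGIT+", "PD-1-", "CD45RA-"),
                           total_frequency=0.20, timepoint="t1")
        b1 = ExpansionCall((0,), "Vb22", 0.9, ("TIGIT-", "PD-1+", "CD45RA-"),
                           total_frequency=0.12, timepoint="t2")
        b2 = ExpansionCall((1,), "Vb22", 0.8, ("TIGIT+", "PD-1-", "CD45RA-"),
                           total_frequency=0.22, timepoint="t2")
        kin = expansion_kinetics({"t1": [a1, a2], "t2": [b1, b2]})
        assert len(kin) == 2
        by_fp = kin.set_index("fingerprint")
        assert by_fp.loc["TIGIT-/PD-1+/CD45RA-", "t2"] == 0.12
        assert by_fp.loc["TIGIT+/PD-1-/CD45RA-", "t2"] == 0.22


class TestRecoveryFromGenerator:
    def test_planted_clone_frequency_recovered(self, panel):
        """Tube-relative frequency of a planted 80% clone is recovered
        within binomial error from generator output."""
        means, sds = _phenotype(("CD3", "CD4"))
        poly = reference_vb_distribution(panel.families)
        manifest = GroundTruthManifest(
            populations=[
                PopulationSpec("clone", "late_memory_CD4", 0.8, means, sds,
                               "Vb13.2"),
                PopulationSpec("poly", "late_memory_CD4", 0.2, means, sds,
                               dict(poly)),
            ],
            seed=0,
        )
        tubes = simulate_sample(manifest, panel, 10_000, seed=17)
        meta = pd.concat(
            [
                pd.DataFrame(
                    {"tube_id": t.tube_id, "vb_label": t.gate_labels}
                )
                for t in tubes
            ],
            ignore_index=True,
        )
        prof = vb_profile(meta, panel, scope="late_memory")
        expected = 0.8 + 0.2 * poly["Vb13.2"]
        got = prof.table.loc["Vb13.2", "tube_relative_freq"]
        assert got == pytest.approx(expected, abs=0.02)
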