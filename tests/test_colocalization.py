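"""Hotspot-lesion contact rules, subgroup eligibility and cohort summaries."""
import numpy as np
import pandas as pd
import pytest

import bbbhotspots as b
from bbbhotspots.colocalization import LesionSet
from bbbhotspots.masks import AnalysisMasks


def brute_force_band(mask):
    out = np.zeros_like(mask)
    for idx in np.argwhere(~mask):
        i, j, k = idx
        lo = np.maximum(idx - 1, 0)
        hi = np.minimum(idx + 2, mask.shape)
        if mask[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]].any():
            out[i, j, k] = True
    return out


def _lesions(shape=(12, 12, 12), lacune=None, wmh=None, cmb=None):
    lac = np.zeros(shape, np.int32)
    w = np.zeros(shape, bool)
    c = np.zeros(shape, np.int32)
    if lacune is not None:
        lac[lacune] = 1
    if wmh is not None:
        w[wmh] = True
    if cmb is not None:
        c[cmb] = 1
    return LesionSet(lacunes=lac, wmh=w, cmbs=c)


class TestOuterBand:
    def test_single_voxel_band_is_26_neighbors(self):
        mask = np.zeros((5, 5, 5), bool)
        mask[2, 2, 2] = True
        band = b.outer_band(mask)
        assert band.sum() == 26
        assert not band[2, 2, 2]

    def test_empty_mask_empty_band(self):
        assert b.outer_band(np.zeros((4, 4, 4), bool)).sum() == 0

    def test_digital_sphere_matches_brute_force(self):
        x, y, z = np.mgrid[:14, :14, :14] - 6.5
        mask = x**2 + y**2 + z**2 <= 9
        np.testing.assert_array_equal(b.outer_band(mask), brute_force_band(mask))
        # band disjoint from the lesion itself
        assert not (b.outer_band(mask) & mask).any()


class TestClassifyHotspot:
    def test_hotspot_in_lacune_band_is_at_edge(self):
        lesions = _lesions(lacune=(5, 5, 5))
        flags = b.classify_hotspot(np.array([[5, 5, 6], [5, 5, 7], [5, 5, 8]]), lesions)
        assert flags.at_lacune_edge
        assert flags.lacune_ids == (1,)
        assert not flags.at_cmb_edge

    def test_hotspot_far_from_lacune_not_flagged(self):
        lesions = _lesions(lacune=(1, 1, 1))
        flags = b.classify_hotspot(np.array([[8, 8, 8]]), lesions)
        assert not flags.at_lacune_edge

    def test_within_wmh_requires_full_containment(self):
        wmh = (slice(3, 9), slice(3, 9), slice(3, 9))
        lesions = _lesions(wmh=wmh)
        interior = np.array([[5, 5, 5], [5, 5, 6], [6, 5, 5]])
        f_in = b.classify_hotspot(interior, lesions)
        assert f_in.within_wmh and not f_in.at_wmh_edge
        straddling = np.array([[2, 5, 5], [3, 5, 5], [4, 5, 5]])
        f_edge = b.classify_hotspot(straddling, lesions)
        assert f_edge.at_wmh_edge and not f_edge.within_wmh

    def test_flags_can_combine_across_lesion_classes(self):
        # a hotspot fully inside WMH that also touches a lacune band
        lesions = _lesions(lacune=(5, 5, 2), wmh=(slice(3, 9), slice(3, 9), slice(3, 9)))
        vox = np.array([[5, 5, 3], [5, 5, 4]])
        flags = b.classify_hotspot(vox, lesions)
        assert flags.within_wmh and flags.at_lacune_edge

    def test_majority_containment_option(self):
        lesions = _lesions(wmh=(slice(3, 9), slice(3, 9), slice(3, 9)))
        vox = np.array([[2, 5, 5], [3, 5, 5], [4, 5, 5]])  # 2 of 3 inside
        f = b.classify_hotspot(vox, lesions, wmh_containment="majority")
        assert f.within_wmh and not f.at_wmh_edge

    def test_translation_invariance(self):
        lesions = _lesions((16, 16, 16), lacune=(5, 5, 5))
        vox = np.array([[5, 5, 6], [5, 5, 7]])
        f1 = b.classify_hotspot(vox, lesions)
        shifted = _lesions((16, 16, 16), lacune=(8, 8, 8))
        f2 = b.classify_hotspot(vox + 3, shifted)
        assert (f1.at_lacune_edge, f1.within_wmh, f1.at_wmh_edge) == (
            f2.at_lacune_edge,
            f2.within_wmh,
            f2.at_wmh_edge,
        )


class TestSubgroupEligibility:
    def _masks(self, shape=(12, 12, 12), nawm_fraction=0.9):
        wm = np.ones(shape, bool)
        wmh = np.zeros(shape, bool)
        n_wmh = int(wm.sum() * (1 - nawm_fraction))
        wmh.ravel()[:n_wmh] = True
        return AnalysisMasks(
            wm_all=wm, wm_eroded=wm.copy(), nawm=wm & ~wmh, wmh=wmh, wm_eroded_filled=wm.copy()
        )

    def test_minimal_wmh_load_excluded(self):
        masks = self._masks()
        lesions = _lesions()
        flags = b.subgroup_eligibility(lesions, masks, fazekas_dwmh=0, fazekas_pvh=1)
        assert not flags["wmh_subgroup"]
        flags = b.subgroup_eligibility(lesions, masks, fazekas_dwmh=1, fazekas_pvh=1)
        assert flags["wmh_subgroup"]

    def test_minimal_nawm_left_excluded(self):
        masks = self._masks(nawm_fraction=0.05)
        flags = b.subgroup_eligibility(_lesions(), masks, fazekas_dwmh=3, fazekas_pvh=3)
        assert not flags["wmh_subgroup"]

    def test_deep_lacune_triggers_lacune_subgroup(self):
        masks = self._masks()
        lesions = _lesions(lacune=(6, 6, 6))
        flags = b.subgroup_eligibility(lesions, masks, 1, 1)
        assert flags["lacune_subgroup"]
        assert not flags["cmb_subgroup"]

    def test_invalid_grade_rejected(self):
        with pytest.raises(ValueError, match="fazekas"):
            b.subgroup_eligibility(_lesions(), self._masks(), 4, 1)


class TestSummaries:
    def test_presence_fraction_of_two_patient_cohort(self):
        lesions = _lesions(lacune=(5, 5, 5))
        hot = b.classify_hotspot(np.array([[5, 5, 6]]), lesions, hotspot_id=1)
        cold = b.classify_hotspot(np.array([[9, 9, 9]]), lesions, hotspot_id=1)
        from bbbhotspots.colocalization import ColocalizationTable

        tables = {
            "a": ColocalizationTable([hot], lacunes_with_hotspot={1}),
            "b": ColocalizationTable([cold]),
        }
        elig = {p: {"lacune_subgroup": True, "wmh_subgroup": False, "cmb_subgroup": False} for p in tables}
        s = b.summarize_colocalization(tables, elig).set_index("category")
        row = s.loc["at_lacune_edge"]
        assert row["n_eligible"] == 2
        assert row["n_with_hotspot"] == 1
        assert row["presence_fraction"] == 0.5
        assert s.loc["within_wmh", "no_eligible_patients"]

    def test_cohort_fractions_match_hand_tally(self, lesion_phantom, truth_maps, noisy_maps):
        hs = b.detect_hotspots(
            np.where(np.isfinite(noisy_maps.ps), noisy_maps.ps, 0.0),
            noisy_maps.fit_mask,
            lesion_phantom.atlas,
        )
        lesions = LesionSet.from_phantom(lesion_phantom)
        table = b.classify_hotspot_set(hs, lesions)
        df = table.to_frame()
        for cat in ("at_lacune_edge", "within_wmh", "at_wmh_edge", "at_cmb_edge"):
            assert table.count(cat) == int(df[cat].sum())
        # per-lesion monotonicity: touched lesions only accumulate
        partial = b.classify_hotspot_set(
            b.HotspotSet(hs.hotspots[: hs.count // 2], hs.threshold_value, 0, 0), lesions
        )
        assert partial.lacunes_with_hotspot <= table.lacunes_with_hotspot

    def test_within_wmh_implies_every_voxel_in_wmh(self, lesion_phantom, noisy_maps):
        hs = b.detect_hotspots(
            np.where(np.isfinite(noisy_maps.ps), noisy_maps.ps, 0.0),
            noisy_maps.fit_mask,
            lesion_phantom.atlas,
        )
        lesions = LesionSet.from_phantom(lesion_phantom)
        table = b.classify_hotspot_set(hs, lesions)
        by_id = {h.id: h for h in hs.hotspots}
        for f in table.flags:
            if f.within_wmh:
                vox = by_id[f.hotspot_id].voxels
                assert lesions.wmh[tuple(vox.T)].all()
            assert not (f.within_wmh and f.at_wmh_edge)
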