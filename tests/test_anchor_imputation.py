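"""Anchor finding, weighted transfer, timecourse assembly."""

import dataclasses

import numpy as np
import pytest

from spacetrace import synthetic_tissue as st
from spacetrace.anchor_imputation import (
    AnchorParams,
    find_anchors,
    integrate_timecourse,
    transfer,
)
from spacetrace.cell_typing import to_counts
from spacetrace.errors import AnchorError, ValidationError
from spacetrace.msi_data import tic_normalize
from spacetrace.validation import split_half


@pytest.fixture(scope="module")
def two_halves(small_dataset, lipid_ids):
    """Bisected labeled section: counts, types and normalized halves."""
    control, labeled, truth = small_dataset
    sec = labeled[-1]  # t = 120 min section
    types = truth.type_maps[sec.section_id]
    mask_a = sec.coords[:, 0] < np.median(sec.coords[:, 0])
    a, b = split_half(sec)
    an, bn = tic_normalize(a), tic_normalize(b)
    idx_a = [an.feature_index(f) for f in lipid_ids]
    idx_b = [bn.feature_index(f) for f in lipid_ids]
    qc = to_counts(an.intensities)[:, idx_a]
    rc = to_counts(bn.intensities)[:, idx_b]
    return qc, rc, types[mask_a], types[~mask_a], an, bn


class TestFindAnchors:
    def test_identity_query_anchors_to_itself(self, two_halves):
        qc = two_halves[0][:300]
        anchors = find_anchors(qc, qc, AnchorParams(seed=0))
        self_pairs = {
            q for q, r in anchors.pairs if q == r
        }
        assert len(self_pairs) >= 0.95 * qc.shape[0]

    def test_anchor_purity_on_synthetic_types(self, two_halves):
        qc, rc, ta, tb, *_ = two_halves
        anchors = find_anchors(qc, rc, AnchorParams(seed=0))
        purity = (ta[anchors.pairs[:, 0]] == tb[anchors.pairs[:, 1]]).mean()
        assert purity >= 0.95

    def test_disjoint_archetypes_raise_anchor_error(self):
        # apples and oranges live on disjoint feature supports: any mutual
        # nearest neighbors fail the similarity filter -> zero anchors
        rng = np.random.default_rng(0)
        apples = np.hstack(
            [rng.uniform(20, 60, size=(60, 4)), np.zeros((60, 4))]
        )
        oranges = np.hstack(
            [np.zeros((60, 4)), rng.uniform(20, 60, size=(60, 4))]
        )
        with pytest.raises(AnchorError):
            find_anchors(apples, oranges, AnchorParams(k_anchor=3, seed=0))

    def test_mismatched_feature_count_errors(self):
        with pytest.raises(AnchorError, match="feature"):
            find_anchors(np.ones((30, 4)), np.ones((30, 5)))

    def test_scores_within_unit_interval(self, two_halves):
        qc, rc, *_ = two_halves
        anchors = find_anchors(qc, rc, AnchorParams(seed=0))
        assert anchors.scores.min() >= 0 and anchors.scores.max() <= 1


class TestTransfer:
    def test_constant_reference_imputes_constant(self, two_halves):
        qc, rc, *_ = two_halves
        anchors = find_anchors(qc, rc, AnchorParams(seed=0))
        values = np.full(rc.shape[0], 3.7)
        out = transfer(anchors, values)
        np.testing.assert_allclose(out, 3.7)

    def test_self_transfer_identity_exact(self, two_halves):
        qc = two_halves[0][:300]
        anchors = find_anchors(qc, qc, AnchorParams(seed=0))
        rng = np.random.default_rng(3)
        values = rng.uniform(0, 5, size=(qc.shape[0], 3))
        out = transfer(anchors, values, k_weight=1)
        np.testing.assert_allclose(out, values, atol=1e-12)

    def test_imputed_values_are_convex_combinations(self, two_halves):
        qc, rc, *_ = two_halves
        anchors = find_anchors(qc, rc, AnchorParams(seed=0))
        rng = np.random.default_rng(4)
        values = rng.uniform(1, 9, size=rc.shape[0])
        out = transfer(anchors, values)
        referenced = values[np.unique(anchors.pairs[:, 1])]
        assert out.min() >= referenced.min() - 1e-9
        assert out.max() <= referenced.max() + 1e-9

    def test_reference_order_invariance(self):
        # continuous profiles and k_anchor=1 (a matching, so anchor query
        # members are unique and no selection ties exist): the anchor set
        # and imputed values ignore reference pixel order
        rng = np.random.default_rng(5)
        base = rng.lognormal(2.0, 1.0, size=(250, 20))
        qc = base * rng.lognormal(0, 0.1, size=base.shape)
        rc = base * rng.lognormal(0, 0.1, size=base.shape)
        perm = rng.permutation(rc.shape[0])
        values = rng.uniform(0, 5, size=rc.shape[0])
        params = AnchorParams(k_anchor=1, k_weight=20, seed=0)
        out1 = transfer(find_anchors(qc, rc, params), values)
        out2 = transfer(find_anchors(qc, rc[perm], params), values[perm])
        np.testing.assert_allclose(out1, out2, atol=1e-6)

    def test_k_weight_clamped_with_warning(self, two_halves):
        qc = two_halves[0][:100]
        anchors = find_anchors(qc, qc, AnchorParams(seed=0))
        with pytest.warns(UserWarning, match="clamp"):
            transfer(anchors, np.ones(qc.shape[0]), k_weight=10**6)


class TestIntegrateTimecourse:
    def test_assembles_blocks_per_tracer_timepoint(
        self, small_dataset, lipid_ids
    ):
        control, labeled, _ = small_dataset
        cn = tic_normalize(control)
        ln = [tic_normalize(pm) for pm in labeled]
        ds = integrate_timecourse(cn, ln, lipid_ids)
        keys = set(ds.blocks)
        # 4 labeled timepoints plus the control-derived t=0 block
        assert keys == {("glc13", t) for t in (0.0, 15.0, 30.0, 60.0, 120.0)}
        for values, ids in ds.blocks.values():
            assert values.shape == (control.n_pixels, len(ids))
            assert np.all(values >= 0)

    def test_t0_block_copies_control_metabolites(
        self, small_dataset, lipid_ids
    ):
        control, labeled, _ = small_dataset
        cn = tic_normalize(control)
        ds = integrate_timecourse(
            cn, [tic_normalize(labeled[0])], lipid_ids
        )
        vals, ids = ds.blocks[("glc13", 0.0)]
        expected = cn.subset_features(ids).intensities
        np.testing.assert_allclose(vals, expected)

    def test_empty_labeled_list_gives_no_blocks(
        self, small_dataset, lipid_ids
    ):
        control, _, _ = small_dataset
        ds = integrate_timecourse(tic_normalize(control), [], lipid_ids)
        assert ds.blocks == {}

    def test_missing_tracer_metadata_errors(self, small_dataset, lipid_ids):
        control, labeled, _ = small_dataset
        bad = dataclasses.replace(tic_normalize(labeled[0]), tracer="none")
        with pytest.raises(ValidationError, match="tracer"):
            integrate_timecourse(tic_normalize(control), [bad], lipid_ids)

    def test_duplicate_key_errors(self, small_dataset, lipid_ids):
        control, labeled, _ = small_dataset
        pm = tic_normalize(labeled[0])
        with pytest.raises(ValidationError, match="duplicate"):
            integrate_timecourse(tic_normalize(control), [pm, pm], lipid_ids)
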