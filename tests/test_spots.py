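"""Spot detection, K-means intensity gating, and codebook decoding."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from conftest import make_spot_table
from oracles import brute_optimal_split_wcss, brute_two_means_wcss
from scmst.errors import DecodingError, ValidationError
from scmst.spots import (
    Codebook,
    decode_gene,
    detect_spots,
    kmeans_signal_gate,
    optimal_1d_two_means,
)


class TestCodebook:
    def test_thirty_gene_panel_spans_six_rounds_of_five(self):
        genes = [f"g{i}" for i in range(30)]
        cb = Codebook.from_panel(genes, n_rounds=6, channels_per_round=5)
        assert {r for r, _ in cb.entries} == set(range(6))
        assert cb.genes == genes

    def test_lookup(self):
        cb = Codebook({(2, 3): "Pax7"}, n_rounds=6, channels_per_round=5)
        assert cb.lookup(2, 3) == "Pax7"

    def test_unknown_pair_raises(self):
        cb = Codebook.from_panel(["a"], 6, 5)
        with pytest.raises(DecodingError, match="round=7"):
            cb.lookup(7, 1)

    def test_duplicate_gene_rejected(self):
        with pytest.raises(ValidationError, match="injective"):
            Codebook({(0, 0): "A", (0, 1): "A"}, 1, 2)

    def test_panel_exceeding_capacity_rejected(self):
        with pytest.raises(ValidationError):
            Codebook.from_panel(["a", "b", "c"], 1, 2)


class TestDetect:
    def test_empty_volume_empty_table(self):
        det = detect_spots(np.zeros((8, 16, 16)), sigma=1.2, min_peak=1.0)
        assert det.empty

    def test_single_spot_localized_within_one_voxel(self):
        vol = np.zeros((12, 24, 24))
        zz, yy, xx = np.mgrid[0:12, 0:24, 0:24]
        c = (6, 12, 13)
        vol += 1000 * np.exp(
            -0.5 * ((zz - c[0]) ** 2 + ((yy - c[1]) / 1.25) ** 2
                    + ((xx - c[2]) / 1.25) ** 2)
        )
        det = detect_spots(vol, sigma=(1.0, 1.25, 1.25), min_peak=10.0)
        assert len(det) == 1
        got = det[["z", "y", "x"]].to_numpy()[0]
        assert np.abs(got - c).max() <= 1

    def test_count_monotone_in_threshold(self):
        rng = np.random.default_rng(0)
        from scipy import ndimage as ndi

        vol = np.abs(ndi.gaussian_filter(rng.normal(0, 50, (10, 32, 32)), 1.2))
        counts = [
            len(detect_spots(vol, sigma=1.2, min_peak=t))
            for t in (1.0, 3.0, 10.0, 30.0)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValidationError):
            detect_spots(np.zeros((4, 4, 4)), sigma=0.0)


class TestKmeansGate:
    def test_clean_bimodal_split(self):
        table = make_spot_table([100.0] * 50 + [1000.0] * 50)
        out = kmeans_signal_gate(table)
        cls = out["class"].to_numpy()
        assert (cls[:50] == "unspecific").all()
        assert (cls[50:] == "signal").all()

    def test_degenerate_identical_intensities_all_signal(self):
        table = make_spot_table([500.0] * 20)
        with pytest.warns(UserWarning, match="degenerate"):
            out = kmeans_signal_gate(table)
        assert (out["class"] == "signal").all()

    def test_tiny_group_all_signal(self):
        table = make_spot_table([7.0])
        with pytest.warns(UserWarning):
            out = kmeans_signal_gate(table)
        assert (out["class"] == "signal").all()

    def test_gaussian_mixture_misclassification_below_2pct(self):
        rng = np.random.default_rng(0)
        inten = np.concatenate(
            [rng.normal(1000, 100, 500), rng.normal(200, 25, 500)]
        )
        out = kmeans_signal_gate(make_spot_table(inten))
        truth = np.array(["signal"] * 500 + ["unspecific"] * 500)
        assert (out["class"].to_numpy() != truth).mean() <= 0.02

    def test_groups_gated_independently(self):
        """A channel's dim spots stay signal if that channel is unimodal."""
        bright = make_spot_table(
            list(np.linspace(900, 1100, 40)), channel=0
        )
        dim = make_spot_table(list(np.linspace(90, 110, 40)), channel=1)
        out = kmeans_signal_gate(
            pd.concat([bright, dim], ignore_index=True), log_intensity=True
        )
        # within each channel 2-means still splits, but the dim channel's
        # high half is called signal despite being dimmer than channel 0
        dim_cls = out[out.channel == 1]
        assert (dim_cls[dim_cls.intensity > 105]["class"] == "signal").all()

    @given(
        st.lists(
            st.floats(min_value=1.0, max_value=1e4, allow_nan=False),
            min_size=2, max_size=200,
        )
    )
    def test_two_means_equals_exhaustive_contiguous_split(self, values):
        vals = np.array(values)
        mask = optimal_1d_two_means(vals)
        got = brute_two_means_wcss(vals, mask)
        best = brute_optimal_split_wcss(vals) if np.ptp(vals) else 0.0
        assert got <= best + 1e-6 * max(1.0, abs(best))
        # higher-mean side is labeled True
        if mask.any() and (~mask).any():
            assert vals[mask].mean() >= vals[~mask].mean()


class TestDecode:
    def _table(self, pairs):
        rows = []
        for i, (r, c) in enumerate(pairs):
            rows.append(
                dict(spot_id=i, fov=0, round=r, channel=c, gene="", z=0.0,
                     y=0.0, x=0.0, intensity=1.0, **{"class": "signal"},
                     cell_id=0)
            )
        return pd.DataFrame(rows)

    def test_lookup_populates_gene(self):
        cb = Codebook({(2, 3): "Pax7"}, 6, 5)
        out = decode_gene(self._table([(2, 3)]), cb)
        assert out["gene"].tolist() == ["Pax7"]

    def test_unknown_round_raises(self):
        cb = Codebook.from_panel([f"g{i}" for i in range(30)], 6, 5)
        with pytest.raises(DecodingError, match="round=7"):
            decode_gene(self._table([(7, 1)]), cb)

    def test_reference_channel_spots_dropped(self):
        cb = Codebook(
            {(0, 0): "A"}, 1, 2, reference_channels={(0, 1)}
        )
        with pytest.warns(UserWarning, match="dropped 1"):
            out = decode_gene(self._table([(0, 0), (0, 1)]), cb)
        assert len(out) == 1
        assert out["gene"].tolist() == ["A"]


def test_gate_decision_independent_of_cluster_labels():
    """Signal is decided by mean intensity, never by k-means label ids:
    reversing the input order (which permutes internal labels) yields the
    same per-spot classes."""
    rng = np.random.default_rng(3)
    inten = np.concatenate([rng.normal(900, 90, 60), rng.normal(150, 20, 60)])
    fwd = kmeans_signal_gate(make_spot_table(inten))
    rev = kmeans_signal_gate(make_spot_table(inten[::-1]))
    assert fwd["class"].tolist() == rev["class"].tolist()[::-1]
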