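"""dT1 maps, regional roll-ups, GAG estimation and the study table."""

import numpy as np
import pandas as pd
import pytest

from dgemric import (
    EllipseParams,
    RegionDefinition,
    T1Map,
    assign_sectors,
    delta_t1,
    gag_from_delta,
    region_summary,
)
from dgemric.aggregation import DeltaT1Map, build_study_table
from dgemric.errors import IntegrityError, PairingError
from dgemric.relaxometry import SeriesMeta


def _uniform_map(value, mask, meta=None, shape=(16, 16)):
    t1 = np.where(mask, float(value), np.nan)
    return T1Map(
        t1_ms=t1,
        s0=np.where(mask, 1.0, np.nan),
        rss=np.zeros(shape),
        valid=mask.copy(),
        meta=meta or SeriesMeta(subject="A", disc_level="L4/5",
                                timepoint="post-bedrest"),
    )


@pytest.fixture
def mask16():
    m = np.zeros((16, 16), dtype=bool)
    m[4:12, 4:12] = True
    return m


class TestDeltaT1:
    @pytest.mark.parametrize(
        "native,post,expected",
        [
            (766.44, 814.75, -48.31),   # L4/5 after bedrest
            (813.23, 794.80, 18.43),    # L1/2 after bedrest
            (866.15, 766.18, 99.97),    # L3/4 before bedrest
            (1131.38, 972.32, 159.06),  # nucleus center before bedrest
        ],
    )
    def test_published_row_arithmetic(self, mask16, native, post, expected):
        dmap = delta_t1(_uniform_map(native, mask16), _uniform_map(post, mask16))
        assert np.allclose(dmap.delta_ms[mask16], expected, atol=1e-9)

    def test_antisymmetry(self, mask16):
        a, b = _uniform_map(900.0, mask16), _uniform_map(840.0, mask16)
        d1, d2 = delta_t1(a, b), delta_t1(b, a)
        assert np.allclose(d1.delta_ms[mask16], -d2.delta_ms[mask16])

    def test_disjoint_masks_give_empty_valid_set(self):
        m1 = np.zeros((16, 16), dtype=bool)
        m2 = np.zeros((16, 16), dtype=bool)
        m1[0:4], m2[8:12] = True, True
        dmap = delta_t1(_uniform_map(900.0, m1), _uniform_map(800.0, m2))
        assert not dmap.valid.any()

    def test_metadata_mismatch_rejected(self, mask16):
        a = _uniform_map(900.0, mask16)
        b = _uniform_map(800.0, mask16,
                         meta=SeriesMeta(subject="B", disc_level="L4/5",
                                         timepoint="post-bedrest"))
        with pytest.raises(PairingError):
            delta_t1(a, b)

    def test_linearity_of_disc_mean(self, mask16):
        rng = np.random.default_rng(5)
        nat = _uniform_map(0.0, mask16)
        post = _uniform_map(0.0, mask16)
        nat.t1_ms[mask16] = rng.uniform(800, 1000, mask16.sum())
        post.t1_ms[mask16] = rng.uniform(700, 900, mask16.sum())
        dmap = delta_t1(nat, post)
        lhs = dmap.delta_ms[mask16].mean()
        rhs = nat.t1_ms[mask16].mean() - post.t1_ms[mask16].mean()
        assert lhs == pytest.approx(rhs, abs=1e-9)


class TestRegionSummary:
    ell = EllipseParams(center=(32.0, 32.0), semi_axes=(20.0, 12.0),
                        orientation_deg=0.0, anterior_deg=0.0)

    def _labels(self):
        return assign_sectors(self.ell, (64, 64))

    def test_uniform_map_every_region_mean(self):
        labels = self._labels()
        m = _uniform_map(912.5, labels.inside, shape=(64, 64))
        out = region_summary(m, labels)
        got = out[out["n"] > 0]
        assert np.allclose(got["mean"], 912.5)
        assert np.allclose(got.loc[got["n"] >= 2, "sd"], 0.0)

    def test_six_pixel_toy_matches_hand_arithmetic(self):
        # two sectors, values 1,2,3 and 4,5,6: means 2 and 5, sd 1 and 1
        labels = self._labels()
        ring, wedge = labels.ring, labels.wedge
        sel_a = np.argwhere((ring == 3) & (wedge == 0))[:3]
        sel_b = np.argwhere((ring == 3) & (wedge == 6))[:3]
        m = _uniform_map(0.0, np.zeros((64, 64), dtype=bool), shape=(64, 64))
        for (r, c), v in zip(sel_a, [1.0, 2.0, 3.0]):
            m.t1_ms[r, c] = v
            m.valid[r, c] = True
        for (r, c), v in zip(sel_b, [4.0, 5.0, 6.0]):
            m.t1_ms[r, c] = v
            m.valid[r, c] = True
        out = region_summary(m, labels).set_index(["region_type", "region"])
        assert out.loc[("sector", "r3w0"), "mean"] == pytest.approx(2.0)
        assert out.loc[("sector", "r3w0"), "sd"] == pytest.approx(1.0)
        assert out.loc[("sector", "r3w6"), "mean"] == pytest.approx(5.0)
        assert out.loc[("disc", "disc"), "mean"] == pytest.approx(3.5)
        assert out.loc[("disc", "disc"), "n"] == 6

    def test_empty_region_reported_missing_not_zero(self):
        labels = self._labels()
        m = _uniform_map(900.0, np.zeros((64, 64), dtype=bool), shape=(64, 64))
        out = region_summary(m, labels).set_index(["region_type", "region"])
        row = out.loc[("disc", "disc")]
        assert row["n"] == 0 and np.isnan(row["mean"])

    def test_two_slices_pool_at_pixel_level(self):
        labels = self._labels()
        m1 = _uniform_map(900.0, labels.inside, shape=(64, 64))
        m2 = _uniform_map(800.0, labels.inside, shape=(64, 64))
        out = region_summary([m1, m2], [labels, labels])
        disc = out.set_index(["region_type", "region"]).loc[("disc", "disc")]
        assert disc["mean"] == pytest.approx(850.0)
        assert disc["n"] == 2 * labels.inside.sum()

    def test_rollups_are_convex_combinations(self):
        labels = self._labels()
        rng = np.random.default_rng(8)
        m = _uniform_map(0.0, labels.inside, shape=(64, 64))
        m.t1_ms[labels.inside] = rng.uniform(500, 1400, labels.inside.sum())
        out = region_summary(m, labels)
        sectors = out[(out["region_type"] == "sector") & (out["n"] > 0)]
        disc = out[out["region_type"] == "disc"]["mean"].iloc[0]
        assert sectors["mean"].min() <= disc <= sectors["mean"].max()
        # weighted mean of sector means equals the disc mean
        w = (sectors["mean"] * sectors["n"]).sum() / sectors["n"].sum()
        assert disc == pytest.approx(w, rel=1e-12)

    def test_anterior_posterior_restricted_to_annulus(self):
        labels = self._labels()
        m = _uniform_map(0.0, labels.inside, shape=(64, 64))
        m.t1_ms[labels.inside] = 1.0
        # give nucleus pixels a huge value: anterior mean must ignore them
        m.t1_ms[np.isin(labels.ring, [1, 2])] = 1e6
        out = region_summary(m, labels).set_index(["region_type", "region"])
        assert out.loc[("zone", "anterior"), "mean"] == pytest.approx(1.0)
        assert out.loc[("zone", "posterior"), "mean"] == pytest.approx(1.0)


class TestGag:
    def test_intercept(self):
        assert gag_from_delta(0.0) == pytest.approx(238.0)

    def test_direct_arithmetic(self):
        assert gag_from_delta(100.0) == pytest.approx(100.0)

    def test_post_bedrest_study_mean(self):
        # study-level post-bedrest mean dT1 of -20.20 ms
        assert gag_from_delta(-20.20) == pytest.approx(265.876)

    def test_strictly_decreasing(self):
        x = np.linspace(-100, 300, 201)
        y = gag_from_delta(x)
        assert np.all(np.diff(y) < 0)


class TestStudyTable:
    def _record(self, subject, level, tp, region="disc"):
        return {
            "subject": subject, "disc_level": level, "timepoint": tp,
            "measure": "delta_t1", "region_type": "disc", "region": region,
            "mean": 100.0, "sd": 10.0, "n": 50,
        }

    def test_counting(self):
        recs = [
            self._record(s, l, tp)
            for s in "ABCDE"
            for l in ("L1/2", "L2/3", "L3/4", "L4/5")
            for tp in ("pre-bedrest", "post-bedrest")
        ]
        table = build_study_table(recs)
        assert len(table) == 5 * 4 * 2

    def test_duplicates_rejected(self):
        recs = [self._record("A", "L1/2", "pre-bedrest")] * 2
        with pytest.raises(IntegrityError):
            build_study_table(recs)

    def test_empty_input_valid_schema(self):
        table = build_study_table([])
        assert len(table) == 0
        assert "measure" in table.columns
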