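import numpy as np
import pytest

from reprt import (
    CalibrantSet,
    RTTable,
    build_context,
    calibrate,
    quality_estimate,
    r_squared,
    select_reference,
)


def _table_from_wide(wide_dict, molecules):
    records = [
        (m, cm, rts[i]) for cm, rts in wide_dict.items() for i, m in enumerate(molecules)
    ]
    return RTTable.from_records(records)


@pytest.fixture(scope="module")
def toy():
    """Three CMs where cmB is an affine map of cmA and cmC is warped."""
    rng = np.random.default_rng(5)
    molecules = [f"m{i:02d}" for i in range(30)]
    base = np.sort(rng.uniform(1, 18, 30))
    wide = {
        "cmA": base,
        "cmB": 1.5 * base + 2.0,
        "cmC": 2 + 20 / (1 + np.exp(-0.35 * (base - 9))),
    }
    table = _table_from_wide(wide, molecules)
    cal = CalibrantSet("toy", tuple(molecules[::3]))
    return molecules, table, cal


class TestSelectReference:
    def test_affine_candidate_wins_with_unit_r2(self, toy):
        molecules, table, cal = toy
        reicm, r2c = select_reference("cmA", ["cmB", "cmC"], table, cal)
        assert reicm == "cmB"
        assert r2c == pytest.approx(1.0)

    def test_tie_breaks_to_lexicographically_smaller(self, toy):
        molecules, table, cal = toy
        # duplicate cmB under two names: identical r2 -> smaller id wins
        dup = table.df[table.df["cm_id"] == "cmB"].assign(cm_id="cmD")
        table2 = RTTable(
            __import__("pandas").concat([table.df, dup], ignore_index=True)
        )
        reicm, _ = select_reference("cmA", ["cmD", "cmB"], table2, cal)
        assert reicm == "cmB"

    def test_no_covered_candidate_raises(self, toy):
        molecules, table, cal = toy
        # drop calibrant rows from the only candidate CM
        df = table.df[
            ~(
                (table.df["cm_id"] == "cmB")
                & table.df["molecule_id"].isin(cal.molecule_ids)
            )
        ]
        partial = RTTable(df.reset_index(drop=True))
        with pytest.raises(ValueError, match="no ReICM candidate"):
            select_reference("cmA", ["cmB"], partial, cal)


class TestBuildContext:
    def test_degenerate_reference_equals_input_method(self, toy):
        molecules, table, cal = toy
        ctx = build_context("cmA", "cmA", "cmC", table, cal, seed=0, n_restarts=2)
        assert ctx.r2_c == pytest.approx(1.0)
        x = {m: table.rt(m, "cmA") for m in molecules}
        preds = calibrate(ctx, x, x)
        # main and re models saw identical data: RePRT tracks the projection
        for p in preds:
            assert p.err_after < 0.5

    def test_low_similarity_flag(self, toy):
        molecules, table, cal = toy
        rng = np.random.default_rng(9)
        # a reference method with scrambled elution order
        noise_cm = table.df[table.df["cm_id"] == "cmA"].assign(
            cm_id="cmN", rt=lambda d: rng.permutation(d["rt"].to_numpy())
        )
        table2 = RTTable(__import__("pandas").concat([table.df, noise_cm], ignore_index=True))
        ctx = build_context("cmA", "cmN", "cmC", table2, cal, seed=0, n_restarts=2)
        assert ctx.low_similarity
        assert ctx.r2_c < 0.95

    def test_icm_overrides_support_predicted_calibrant_rts(self, toy):
        molecules, table, cal = toy
        # drop two calibrants from the ICM; provide predicted RTs instead
        dropped = list(cal.molecule_ids[:2])
        df = table.df[
            ~(
                table.df["molecule_id"].isin(dropped)
                & (table.df["cm_id"] == "cmA")
            )
        ]
        table2 = RTTable(df.reset_index(drop=True))
        overrides = {m: table.rt(m, "cmA") + 0.1 for m in dropped}
        ctx = build_context("cmA", "cmB", "cmC", table2, cal,
                            calibrant_rt_overrides=overrides, seed=0, n_restarts=2)
        assert set(ctx.calibrant_set.molecule_ids) == set(cal.molecule_ids)

    def test_insufficient_calibrants_lists_missing(self, toy):
        molecules, table, cal = toy
        df = table.df[~table.df["molecule_id"].isin(cal.molecule_ids[:-3])]
        with pytest.raises(ValueError, match="missing"):
            build_context("cmA", "cmB", "cmC", RTTable(df.reset_index(drop=True)), cal)

    def test_r2_diagnostics_match_raw_pearson(self, toy):
        # oracle equivalence: context r2s equal metrics.r_squared on raw vectors
        molecules, table, cal = toy
        ctx = build_context("cmA", "cmB", "cmC", table, cal, seed=0, n_restarts=2)
        ids = ctx.calibrant_set.molecule_ids
        a = table.rts_in_cm("cmA", ids)
        b = table.rts_in_cm("cmB", ids)
        c = table.rts_in_cm("cmC", ids)
        assert ctx.r2_b == pytest.approx(r_squared(a, c))
        assert ctx.r2_c == pytest.approx(r_squared(a, b))


class TestCalibrate:
    def test_identity_methods_give_near_zero_error(self):
        molecules = [f"m{i:02d}" for i in range(20)]
        rng = np.random.default_rng(1)
        base = np.sort(rng.uniform(1, 15, 20))
        table = _table_from_wide({"c1": base, "c2": base, "c3": base}, molecules)
        cal = CalibrantSet("id", tuple(molecules[::2]))
        ctx = build_context("c1", "c2", "c3", table, cal, seed=0, n_restarts=2)
        x = {m: table.rt(m, "c1") for m in molecules}
        preds = calibrate(ctx, x, x)
        assert max(p.err_after for p in preds) < 0.5

    def test_missing_unknowns_skipped_not_fatal(self, toy):
        molecules, table, cal = toy
        ctx = build_context("cmA", "cmB", "cmC", table, cal, seed=0, n_restarts=2)
        preds = calibrate(
            ctx,
            {"m00": table.rt("m00", "cmA"), "mXX": 5.0},
            {"m00": table.rt("m00", "cmB")},
        )
        assert [p.molecule_id for p in preds] == ["m00"]

    def test_equivariant_to_molecule_relabeling(self, toy):
        molecules, table, cal = toy
        ctx = build_context("cmA", "cmB", "cmC", table, cal, seed=0, n_restarts=2)
        x_icm = {m: table.rt(m, "cmA") for m in molecules[:8]}
        x_re = {m: table.rt(m, "cmB") for m in molecules[:8]}
        preds = calibrate(ctx, x_icm, x_re)
        relabel = {m: f"z_{m}" for m in molecules[:8]}
        preds2 = calibrate(
            ctx,
            {relabel[m]: v for m, v in x_icm.items()},
            {relabel[m]: v for m, v in x_re.items()},
        )
        for p, q in zip(preds, preds2):
            assert q.molecule_id == relabel[p.molecule_id]
            assert q.projected_rt == p.projected_rt
            assert q.err_after == p.err_after

    def test_cross_family_distortion_is_calibrated_away(self, small_dataset):
        # ICM and OCM in different synthetic mobile-phase families, ReICM in
        # the ICM's family: RePRT must beat the experimental-RT comparison
        _, table, cms, truth = small_dataset
        fams = {c.cm_id: c.additive_family for c in cms}
        by_fam = {}
        for cm, f in fams.items():
            by_fam.setdefault(f, []).append(cm)
        f_in, f_out = sorted(by_fam)[0], sorted(by_fam)[-1]
        icm, reicm = by_fam[f_in][0], by_fam[f_in][1]
        ocm = by_fam[f_out][0]
        molecules = table.molecules
        cal = CalibrantSet("syn", tuple(molecules[::4]))
        ctx = build_context(icm, reicm, ocm, table, cal, seed=0, n_restarts=3)
        unknowns = [m for m in molecules if m not in cal.molecule_ids]
        preds = calibrate(
            ctx,
            {m: table.rt(m, icm) for m in unknowns},
            {m: table.rt(m, reicm) for m in unknowns},
            ocm_experimental={m: table.rt(m, ocm) for m in unknowns},
        )
        err_after = np.median([p.err_after for p in preds])
        err_before = np.median([p.err_before for p in preds])
        assert err_after < err_before


class TestQualityEstimate:
    def test_high_confidence_band(self):
        adv = quality_estimate(0.99, 0.999, "B")
        assert adv.band == "high" and adv.reliable
        assert "3.0%" in adv.message

    def test_low_band_warns(self):
        adv = quality_estimate(0.8, 0.5, "B")
        assert adv.band == "low"

    def test_monotone_banding(self):
        order = {"low": 0, "moderate": 1, "high": 2}
        bands = [quality_estimate(0.9, r2c).band for r2c in (0.3, 0.96, 0.995)]
        assert [order[b] for b in bands] == sorted(order[b] for b in bands)

    def test_unrepresentative_set_flagged_unreliable(self):
        adv = quality_estimate(0.99, 0.997, "E")
        assert not adv.reliable
        assert "unreliable" in adv.message

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            quality_estimate(1.2, 0.5)
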