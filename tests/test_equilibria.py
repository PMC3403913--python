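import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from apcva import (
    Ligand,
    MembraneCompetition,
    PairwiseProblem,
    TernaryPreincubation,
    effective_apc,
    membrane_bound_fractions,
    pairwise_complex,
    ternary_preincubation,
)

conc = st.floats(min_value=1e-12, max_value=1e-5)
kd_st = st.floats(min_value=1e-11, max_value=1e-5)


class TestPairwise:
    @pytest.mark.parametrize(
        "a,b,kd,expected,tol",
        [
            # preformed prothrombinase, 200 pM FVa + 100 pM FXa
            (0.2e-9, 0.1e-9, 0.5e-9, 26e-12, 0.5e-12),
            (0.2e-9, 0.1e-9, 0.1e-9, 58.8e-12, 0.5e-12),
            # saturating FXa*: 20 nM FVa + 30 nM FXa
            (20e-9, 30e-9, 0.5e-9, 19.1e-9, 0.05e-9),
            (20e-9, 30e-9, 0.1e-9, 19.8e-9, 0.05e-9),
            # FVa·PT at plasma prothrombin
            (20e-9, 1.4e-6, 700e-9, 13.3e-9, 0.05e-9),
        ],
    )
    def test_printed_preincubation_values(self, a, b, kd, expected, tol):
        assert pairwise_complex(PairwiseProblem(a, b, kd)) == pytest.approx(
            expected, abs=tol
        )

    def test_weak_binding_limit(self):
        a, b = 1e-9, 2e-9
        x = pairwise_complex(PairwiseProblem(a, b, 1.0))  # kd >> totals
        assert x == pytest.approx(a * b / 1.0, rel=1e-6)

    def test_empty_partner_gives_zero(self):
        assert pairwise_complex(PairwiseProblem(1e-9, 0.0, 1e-9)) == 0.0

    @given(a=conc, b=conc, kd=kd_st)
    @settings(max_examples=200, deadline=None)
    def test_symmetry_and_bounds(self, a, b, kd):
        x = pairwise_complex(PairwiseProblem(a, b, kd))
        x_swapped = pairwise_complex(PairwiseProblem(b, a, kd))
        assert x == pytest.approx(x_swapped, rel=1e-12)
        assert 0.0 <= x <= min(a, b) * (1 + 1e-12)

    @given(a=conc, b=conc, kd=kd_st)
    @settings(max_examples=200, deadline=None)
    def test_monotone_in_totals_and_kd(self, a, b, kd):
        x = pairwise_complex(PairwiseProblem(a, b, kd))
        assert pairwise_complex(PairwiseProblem(2 * a, b, kd)) >= x
        assert pairwise_complex(PairwiseProblem(a, b, 2 * kd)) <= x

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            PairwiseProblem(-1e-9, 1e-9, 1e-9)
        with pytest.raises(ValueError):
            PairwiseProblem(1e-9, 1e-9, 0.0)


def _ternary_fixed_point_oracle(p, tol=1e-12, max_iter=200000):
    """Damped fixed-point iteration on the three free concentrations."""
    v, x, pt = p.fva_total, p.fxa_total, p.pt_total
    damp = 0.5
    for _ in range(max_iter):
        xv = x * v / p.kd_xv
        vpt = v * pt / p.kd_v_pt
        xvpt = xv * pt / p.kd_xv_pt
        v_new = p.fva_total / (1 + x / p.kd_xv + pt / p.kd_v_pt
                               + x * pt / (p.kd_xv * p.kd_xv_pt))
        x_new = p.fxa_total / (1 + v / p.kd_xv + v * pt / (p.kd_xv * p.kd_xv_pt))
        pt_new = p.pt_total / (1 + v / p.kd_v_pt + x * v / (p.kd_xv * p.kd_xv_pt))
        v2 = damp * v_new + (1 - damp) * v
        x2 = damp * x_new + (1 - damp) * x
        pt2 = damp * pt_new + (1 - damp) * pt
        if (
            abs(v2 - v) <= tol * max(v, 1e-30)
            and abs(x2 - x) <= tol * max(x, 1e-30)
            and abs(pt2 - pt) <= tol * max(pt, 1e-30)
        ):
            v, x, pt = v2, x2, pt2
            break
        v, x, pt = v2, x2, pt2
    xv = x * v / p.kd_xv
    return {
        "FVa": v,
        "FXa": x,
        "PT": pt,
        "FXa:FVa": xv,
        "FVa:PT": v * pt / p.kd_v_pt,
        "FXa:FVa:PT": xv * pt / p.kd_xv_pt,
    }


class TestTernary:
    def test_modelled_plasma_conditions(self):
        """20 nM FVa + 30 nM FXa* + 1.4 uM PT: ~18.9 nM FVa in prothrombinase
        complexes, ~720 pM in FVa·PT, ~360 pM free."""
        s = ternary_preincubation(TernaryPreincubation(20e-9, 30e-9, 1.4e-6))
        assert s["FXa:FVa"] + s["FXa:FVa:PT"] == pytest.approx(18.9e-9, rel=0.05)
        assert s["FVa:PT"] == pytest.approx(720e-12, rel=0.05)
        assert s["FVa"] == pytest.approx(360e-12, rel=0.05)
        # both prothrombinase pools are populated at t = 0
        assert s["FXa:FVa"] > 1e-9 and s["FXa:FVa:PT"] > 1e-9

    def test_reduces_to_pairwise_without_pt(self):
        s = ternary_preincubation(TernaryPreincubation(20e-9, 30e-9, 0.0))
        xv = pairwise_complex(PairwiseProblem(20e-9, 30e-9, 0.5e-9))
        assert s["FXa:FVa"] == pytest.approx(xv, rel=1e-10)
        assert s["FVa:PT"] == 0.0 and s["FXa:FVa:PT"] == 0.0

    def test_conserves_totals(self):
        p = TernaryPreincubation(20e-9, 30e-9, 1.4e-6)
        s = ternary_preincubation(p)
        assert s["FVa"] + s["FXa:FVa"] + s["FVa:PT"] + s["FXa:FVa:PT"] == pytest.approx(
            p.fva_total, rel=1e-10
        )
        assert s["FXa"] + s["FXa:FVa"] + s["FXa:FVa:PT"] == pytest.approx(
            p.fxa_total, rel=1e-10
        )
        assert s["PT"] + s["FVa:PT"] + s["FXa:FVa:PT"] == pytest.approx(
            p.pt_total, rel=1e-10
        )

    def test_agrees_with_fixed_point_oracle(self, rng):
        for _ in range(20):
            p = TernaryPreincubation(
                fva_total=10 ** rng.uniform(-10, -7),
                fxa_total=10 ** rng.uniform(-10, -7),
                pt_total=10 ** rng.uniform(-9, -5),
                kd_xv=10 ** rng.uniform(-10, -8),
                kd_v_pt=10 ** rng.uniform(-8, -6),
                kd_xv_pt=10 ** rng.uniform(-7, -5),
            )
            got = ternary_preincubation(p)
            want = _ternary_fixed_point_oracle(p)
            for k in got:
                assert got[k] == pytest.approx(want[k], rel=1e-8, abs=1e-20)


def _bisection_site_oracle(m, tol=1e-16):
    lo, hi = 0.0, m.site_total
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        g = mid + sum(
            l.total * mid / (l.kd_membrane + mid) for l in m.ligands
        ) - m.site_total
        if g > 0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


class TestMembraneCompetition:
    def test_default_site_range_matches_lipid_arithmetic(self):
        """20 uM lipid, outer leaflet 2/3 accessible, 30-60 lipids per site
        → 222-444 nM sites."""
        m = MembraneCompetition()
        lo, hi = m.site_range()
        assert lo == pytest.approx(20e-6 * (2 / 3) / 60)
        assert hi == pytest.approx(20e-6 * (2 / 3) / 30)

    def test_apc_crowded_off_membrane_by_prothrombin(self):
        """Across the physiological site range the APC bound fraction brackets
        the modelled ~11 %, PT occupies ~77-78 % of sites, and FVa is almost
        fully bound at the dense end."""
        m = MembraneCompetition()
        lo, hi = m.site_range()
        fracs = []
        for st_ in np.linspace(lo, hi, 9):
            res = membrane_bound_fractions(m.with_site_total(st_))
            fracs.append(res.bound_fraction["APC"])
            assert 0.765 < res.site_occupancy["PT"] < 0.79
        assert min(fracs) <= 0.11 <= max(fracs)
        mid = membrane_bound_fractions(m.with_site_total(0.5 * (lo + hi)))
        assert mid.bound_fraction["APC"] == pytest.approx(0.11, abs=0.03)
        dense = membrane_bound_fractions(m.with_site_total(hi))
        assert dense.bound_fraction["FVa"] > 0.96

    def test_site_balance(self):
        res = membrane_bound_fractions(MembraneCompetition())
        total = res.free_sites + sum(res.bound.values())
        assert total == pytest.approx(res.site_total, rel=1e-12)

    def test_single_ligand_reduces_to_pairwise(self):
        """One ligand competing for sites is the binary binding quadratic
        with the sites as the partner species."""
        m = MembraneCompetition(
            ligands=(Ligand("PT", 1.4e-6, 230e-9),),
            site_total_override=330e-9,
        )
        res = membrane_bound_fractions(m)
        want = pairwise_complex(PairwiseProblem(1.4e-6, 330e-9, 230e-9))
        assert res.bound["PT"] == pytest.approx(want, rel=1e-10)

    def test_agrees_with_bisection_oracle(self, rng):
        for _ in range(20):
            ligands = tuple(
                Ligand(f"L{i}", 10 ** rng.uniform(-9, -5), 10 ** rng.uniform(-9, -6))
                for i in range(3)
            )
            m = MembraneCompetition(
                ligands=ligands, site_total_override=10 ** rng.uniform(-8, -6)
            )
            res = membrane_bound_fractions(m)
            s_oracle = _bisection_site_oracle(m)
            assert res.free_sites == pytest.approx(s_oracle, rel=1e-10, abs=1e-18)

    def test_competition_is_monotone(self):
        base = MembraneCompetition(site_total_override=330e-9)
        res = membrane_bound_fractions(base)
        crowded = MembraneCompetition(
            ligands=(
                Ligand("PT", 2.8e-6, 230e-9),  # doubled competitor
                Ligand("FVa", 20e-9, 2.72e-9),
                Ligand("APC", 2e-9, 500e-9),
            ),
            site_total_override=330e-9,
        )
        res2 = membrane_bound_fractions(crowded)
        assert res2.bound_fraction["APC"] < res.bound_fraction["APC"]
        assert res2.bound_fraction["FVa"] < res.bound_fraction["FVa"]


class TestEffectiveAPC:
    def test_fixed_fraction(self):
        assert effective_apc(2.0e-9, "fixed_fraction") == pytest.approx(0.22e-9)
        assert effective_apc(0.0, "fixed_fraction") == 0.0

    def test_raw_passthrough(self):
        assert effective_apc(5e-9, "raw") == 5e-9

    def test_computed_matches_fixed_fraction_at_dense_sites(self):
        m = MembraneCompetition(
            ligands=(
                Ligand("PT", 1.4e-6, 230e-9),
                Ligand("FVa", 20e-9, 2.72e-9),
                Ligand("APC", 20e-9, 500e-9),
            ),
            site_total_override=385e-9,
        )
        eff = effective_apc(20e-9, "computed", m=m)
        assert eff / 20e-9 == pytest.approx(0.11, abs=0.03)

    def test_computed_requires_membrane(self):
        with pytest.raises(ValueError, match="requires"):
            effective_apc(2e-9, "computed")
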