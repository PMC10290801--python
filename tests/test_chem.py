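"""Formula arithmetic and retro-polyketide decomposition."""

import pytest
from hypothesis import given, settings, strategies as st

from pksmine import chem
from pksmine.chem import (
    BetaState,
    KetideUnit,
    PolyketideChainSpec,
    ReleaseMode,
    decompose_chain,
    format_formula,
    module_tailoring,
    monoisotopic_mass,
    parse_formula,
    retro_compound,
)


class TestFormula:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("C25H38O6", {"C": 25, "H": 38, "O": 6}),
            ("H2O", {"H": 2, "O": 1}),
            ("C25H39O6", {"C": 25, "H": 39, "O": 6}),
            ("CH4", {"C": 1, "H": 4}),
            ("NaCl", {"Na": 1, "Cl": 1}),
        ],
    )
    def test_parse(self, text, expected):
        assert dict(parse_formula(text).counts) == expected

    @pytest.mark.parametrize("bad", ["", "  ", "C0", "Xx5", "C25H38O6!", "25C"])
    def test_parse_rejects_malformed(self, bad):
        with pytest.raises(ValueError):
            parse_formula(bad)

    @given(
        st.dictionaries(
            st.sampled_from(sorted(chem.MONOISOTOPIC_MASS)),
            st.integers(min_value=1, max_value=500),
            min_size=1,
            max_size=6,
        )
    )
    @settings(derandomize=True, max_examples=100)
    def test_format_parse_roundtrip(self, counts):
        formula = chem.MolecularFormula(counts)
        assert dict(parse_formula(format_formula(formula)).counts) == dict(counts)

    def test_hill_order(self):
        assert format_formula(parse_formula("O6H38C25")) == "C25H38O6"
        assert format_formula(parse_formula("ClNa")) == "ClNa"


class TestMonoisotopicMass:
    def test_rasfonin_protonated_cation(self):
        # [M+H]+ of rasfonin, electron-corrected
        f = parse_formula("C25H39O6")
        assert monoisotopic_mass(f, charge=+1) == pytest.approx(435.2741, abs=5e-4)

    def test_carbon_defines_the_unit(self):
        assert monoisotopic_mass(parse_formula("C"), 0) == 12.0

    def test_rasfonin_neutral(self):
        f = parse_formula("C25H38O6")
        assert monoisotopic_mass(f, 0) == pytest.approx(434.2668, abs=5e-4)

    def test_additivity_and_monotonicity(self):
        a = parse_formula("C6H12O6")
        b = parse_formula("N3P2S4")
        assert monoisotopic_mass(a + b, 0) == pytest.approx(
            monoisotopic_mass(a, 0) + monoisotopic_mass(b, 0), abs=1e-9
        )
        bigger = parse_formula("C7H12O6")
        assert monoisotopic_mass(bigger, 0) > monoisotopic_mass(a, 0)


@st.composite
def chain_specs(draw):
    n = draw(st.integers(min_value=1, max_value=12))
    units = [KetideUnit(1, alpha_methyl=draw(st.booleans()), beta_state=BetaState.STARTER)]
    for i in range(2, n + 1):
        units.append(
            KetideUnit(
                i,
                alpha_methyl=draw(st.booleans()),
                beta_state=draw(
                    st.sampled_from(
                        [BetaState.KETONE, BetaState.HYDROXYL, BetaState.ENOYL, BetaState.REDUCED]
                    )
                ),
            )
        )
    release = draw(st.sampled_from(list(ReleaseMode)))
    return PolyketideChainSpec(name="random", units=tuple(units), release=release)


class TestDecomposition:
    @pytest.mark.parametrize(
        "beta,methyl,expected",
        [
            (BetaState.KETONE, False, set()),
            (BetaState.HYDROXYL, False, {"KR"}),
            (BetaState.ENOYL, False, {"KR", "DH"}),
            (BetaState.ENOYL, True, {"KR", "DH", "MT"}),
            (BetaState.REDUCED, False, {"KR", "DH", "ER"}),
            (BetaState.REDUCED, True, {"KR", "DH", "ER", "MT"}),
        ],
    )
    def test_module_tailoring_table(self, beta, methyl, expected):
        assert set(module_tailoring(beta, methyl)) == expected

    def test_starter_has_no_module(self):
        with pytest.raises(ValueError):
            module_tailoring(BetaState.STARTER, False)

    def test_rasfonin_hexaketide(self):
        req = decompose_chain(chem.rasfonin_hexaketide())
        assert req.units == 6
        assert req.extensions == 5
        assert req.methyls == 3
        assert req.required_domains == {"KS", "AT", "DH", "MT", "ER", "KR", "ACP"}

    def test_rasfonin_tetraketide(self):
        req = decompose_chain(chem.rasfonin_tetraketide())
        assert req.units == 4
        assert req.extensions == 3
        assert req.methyls == 2
        assert req.required_domains == {"KS", "AT", "DH", "MT", "ER", "KR", "ACP"}

    def test_starter_only_chain(self):
        spec = PolyketideChainSpec(
            "starter",
            (KetideUnit(1, beta_state=BetaState.STARTER),),
            ReleaseMode.HYDROLYSIS,
        )
        req = decompose_chain(spec)
        assert (req.units, req.extensions) == (1, 0)
        assert req.required_domains == {"KS", "AT", "ACP"}

    @given(chain_specs())
    @settings(derandomize=True, max_examples=100)
    def test_extensions_always_units_minus_one(self, spec):
        req = decompose_chain(spec)
        assert req.extensions == req.units - 1
        assert {"KS", "AT", "ACP"} <= req.required_domains

    @given(chain_specs(), st.integers(min_value=2, max_value=12))
    @settings(derandomize=True, max_examples=60)
    def test_domain_demand_grows_monotonically(self, spec, pick):
        """Deepening a beta-state or adding a methyl never drops a domain."""
        deepen = {
            BetaState.KETONE: BetaState.HYDROXYL,
            BetaState.HYDROXYL: BetaState.ENOYL,
            BetaState.ENOYL: BetaState.REDUCED,
            BetaState.REDUCED: BetaState.REDUCED,
        }
        idx = min(pick, spec.n_units) - 1
        unit = spec.units[idx]
        if unit.beta_state is BetaState.STARTER:
            return
        harder = tuple(
            KetideUnit(u.index, True, deepen[u.beta_state])
            if u.index == unit.index
            else u
            for u in spec.units
        )
        harder_spec = PolyketideChainSpec(spec.name, harder, spec.release)
        assert decompose_chain(spec).required_domains <= (
            decompose_chain(harder_spec).required_domains
        )


class TestRetroCompound:
    def test_rasfonin_carbon_bookkeeping(self):
        spec = chem.rasfonin_compound()
        # 2 x (6 + 4) backbone + 5 methyl carbons = 25
        assert spec.carbon_budget() == 25 == spec.formula["C"]
        report = retro_compound(spec)  # does not raise
        assert {c.chain_name for c in report.chains} == {"hexaketide", "tetraketide"}

    def test_rasfonin_post_pks_demands(self):
        report = retro_compound(chem.rasfonin_compound())
        assert report.post_pks_enzymes["O-acyltransferase"] == 1
        assert report.post_pks_enzymes["trans_thioesterase"] >= 1
        assert report.post_pks_enzymes["cytochrome_p450"] == 2

    def test_carbon_violation_rejected(self):
        bad = chem.CompoundSpec(
            name="bad",
            chains=(chem.rasfonin_hexaketide(),),
            formula=parse_formula("C25H38O6"),
        )
        with pytest.raises(ValueError, match="carbon bookkeeping"):
            retro_compound(bad)

    def test_single_chain_without_ester_needs_no_transacylase(self):
        spec = chem.CompoundSpec(
            name="mono",
            chains=(chem.rasfonin_hexaketide(),),
            formula=parse_formula("C15H24O3"),  # 12 backbone + 3 methyls
        )
        report = retro_compound(spec)
        assert "O-acyltransferase" not in report.post_pks_enzymes


def test_compound_yaml_roundtrip(tmp_path):
    path = tmp_path / "rasfonin.yaml"
    path.write_text(
        """\
name: rasfonin
formula: C25H38O6
ester_links: [[tetraketide, 1]]
post_pks_hydroxylations: [[tetraketide, 8], [tetraketide, 10]]
chains:
  - name: hexaketide
    release: pyrone_cyclization
    units:
      - {beta_state: starter}
      - {beta_state: enoyl}
      - {beta_state: hydroxyl, alpha_methyl: true}
      - {beta_state: reduced, alpha_methyl: true}
      - {beta_state: enoyl, alpha_methyl: true}
      - {beta_state: reduced}
  - name: tetraketide
    release: ester_transfer
    units:
      - {beta_state: starter}
      - {beta_state: reduced, alpha_methyl: true}
      - {beta_state: enoyl, alpha_methyl: true}
      - {beta_state: reduced}
"""
    )
    spec = chem.load_compound(path)
    assert spec == chem.rasfonin_compound()
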