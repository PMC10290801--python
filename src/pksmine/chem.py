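"""Molecular-formula arithmetic and retro-polyketide decomposition.

This module answers the first question of a PKS genome-mining campaign:
given the structure of an acetate-derived polyketide, which enzymatic
machinery must the producing genome encode?  A compound is described as
one or more polyketide chains, each an ordered series of ketide units
annotated with its alpha-methylation and the oxidation state reached at
the beta carbon during chain extension.  Retro-decomposition turns that
description into counts of malonyl-CoA extensions and the minimal PKS
domain inventory (KS/AT/ACP plus KR, DH, ER, MT as the beta-processing
and methylation states demand), together with the post-assembly enzyme
classes (O-acyltransferase for ester linkage of chains, a standalone
trans-acting thioesterase when no intrinsic release domain is implied,
cytochrome P450s for post-PKS hydroxylations).

Monoisotopic masses use an embedded lightest-isotope table (NIST values)
and, for ions, subtract charge x electron mass so that calculated m/z
values match high-resolution ESI-MS conventions.
"""

from __future__ import annotations

import enum
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import yaml

__all__ = [
    "MolecularFormula",
    "parse_formula",
    "format_formula",
    "monoisotopic_mass",
    "BetaState",
    "ReleaseMode",
    "KetideUnit",
    "PolyketideChainSpec",
    "ChainRequirements",
    "CompoundSpec",
    "RetroReport",
    "module_tailoring",
    "decompose_chain",
    "required_domains",
    "retro_compound",
    "load_compound",
    "rasfonin_compound",
    "rasfonin_hexaketide",
    "rasfonin_tetraketide",
    "ELECTRON_MASS",
]

# Monoisotopic (lightest isotope) masses in Da, NIST/CODATA.
MONOISOTOPIC_MASS: Mapping[str, float] = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.99491461956,
    "P": 30.97376163,
    "S": 31.97207100,
    "Na": 22.9897692809,
    "K": 38.96370668479,
    "Cl": 34.96885268,
    "F": 18.99840322,
    "Br": 78.9183371,
    "I": 126.904473,
}

ELECTRON_MASS = 5.48579909e-4  # Da

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class MolecularFormula:
    """Element -> count map, e.g. ``{"C": 25, "H": 38, "O": 6}``.

    Counts are strictly positive; element symbols must be present in the
    embedded isotope-mass table.
    """

    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        frozen = dict(self.counts)
        for element, count in frozen.items():
            if element not in MONOISOTOPIC_MASS:
                raise ValueError(f"unknown element symbol: {element!r}")
            if not isinstance(count, int) or count < 1:
                raise ValueError(
                    f"count for {element} must be a positive integer, got {count!r}"
                )
        object.__setattr__(self, "counts", frozen)

    def __getitem__(self, element: str) -> int:
        return self.counts.get(element, 0)

    def __add__(self, other: "MolecularFormula") -> "MolecularFormula":
        merged = Counter(self.counts)
        merged.update(other.counts)
        return MolecularFormula(dict(merged))

    def mass(self, charge: int = 0) -> float:
        return monoisotopic_mass(self, charge)

    def __str__(self) -> str:
        return format_formula(self)


def parse_formula(text: str) -> MolecularFormula:
    """Parse a Hill-notation formula string such as ``"C25H38O6"``.

    An omitted multiplier means 1.  Raises ``ValueError`` on empty input,
    unknown element symbols or a zero multiplier.
    """
    if not text or not text.strip():
        raise ValueError("empty formula string")
    text = text.strip()
    counts: Counter[str] = Counter()
    pos = 0
    for match in _FORMULA_TOKEN.finditer(text):
        if match.start() != pos:
            raise ValueError(f"malformed formula {text!r} at position {pos}")
        element, digits = match.groups()
        if element not in MONOISOTOPIC_MASS:
            raise ValueError(f"unknown element symbol: {element!r}")
        count = int(digits) if digits else 1
        if count < 1:
            raise ValueError(f"zero multiplier for {element} in {text!r}")
        counts[element] += count
        pos = match.end()
    if pos != len(text):
        raise ValueError(f"malformed formula {text!r} at position {pos}")
    return MolecularFormula(dict(counts))


def format_formula(formula: MolecularFormula) -> str:
    """Canonical Hill notation: C first, H second, then alphabetical."""
    counts = formula.counts

    def fmt(element: str) -> str:
        n = counts[element]
        return element if n == 1 else f"{element}{n}"

    ordered: list[str] = []
    if "C" in counts:
        ordered.append(fmt("C"))
        if "H" in counts:
            ordered.append(fmt("H"))
        rest = sorted(e for e in counts if e not in ("C", "H"))
    else:
        rest = sorted(counts)
    ordered.extend(fmt(e) for e in rest)
    return "".join(ordered)


def monoisotopic_mass(formula: MolecularFormula, charge: int = 0) -> float:
    """Monoisotopic mass in Da; for ions, charge x electron mass is subtracted.

    For a +1 ion this is the m/z of the cation as printed by HR-MS
    software (e.g. [M+H]+ of C25H38O6 is computed from C25H39O6 at
    charge +1).
    """
    mass = sum(MONOISOTOPIC_MASS[el] * n for el, n in formula.counts.items())
    return mass - charge * ELECTRON_MASS


# ---------------------------------------------------------------------------
# Retro-polyketide decomposition
# ---------------------------------------------------------------------------


class BetaState(str, enum.Enum):
    """Oxidation state reached at the beta carbon after one extension cycle."""

    STARTER = "starter"
    KETONE = "ketone"
    HYDROXYL = "hydroxyl"
    ENOYL = "enoyl"
    REDUCED = "reduced"


class ReleaseMode(str, enum.Enum):
    PYRONE_CYCLIZATION = "pyrone_cyclization"
    HYDROLYSIS = "hydrolysis"
    ESTER_TRANSFER = "ester_transfer"


@dataclass(frozen=True)
class KetideUnit:
    """One two-carbon chain segment (index 1 = starter acetate)."""

    index: int
    alpha_methyl: bool = False
    beta_state: BetaState = BetaState.KETONE

    def __post_init__(self) -> None:
        if self.index < 1:
            raise ValueError("unit index is 1-based")
        if (self.index == 1) != (self.beta_state is BetaState.STARTER):
            raise ValueError("exactly the index-1 unit must have beta_state=starter")


@dataclass(frozen=True)
class PolyketideChainSpec:
    name: str
    units: tuple[KetideUnit, ...]
    release: ReleaseMode

    def __post_init__(self) -> None:
        if not self.units:
            raise ValueError(f"chain {self.name!r} has no units")
        indices = [u.index for u in self.units]
        if indices != list(range(1, len(self.units) + 1)):
            raise ValueError(
                f"chain {self.name!r}: unit indices must be contiguous from 1"
            )
        object.__setattr__(self, "units", tuple(self.units))

    @property
    def n_units(self) -> int:
        return len(self.units)

    @property
    def n_methyls(self) -> int:
        return sum(u.alpha_methyl for u in self.units)

    @property
    def backbone_carbons(self) -> int:
        return 2 * self.n_units


@dataclass(frozen=True)
class ChainRequirements:
    """Enzymatic inventory implied by one chain: what the PKS must carry."""

    chain_name: str
    units: int
    extensions: int
    methyls: int
    required_domains: frozenset[str]
    per_module_tailoring: tuple[frozenset[str], ...]

    def __post_init__(self) -> None:
        if self.extensions != self.units - 1:
            raise ValueError("extensions must equal units - 1")
        if not {"KS", "AT", "ACP"} <= self.required_domains:
            raise ValueError("required_domains must include KS, AT and ACP")


CORE_DOMAINS = frozenset({"KS", "AT", "ACP"})

_TAILORING = {
    BetaState.KETONE: frozenset(),
    BetaState.HYDROXYL: frozenset({"KR"}),
    BetaState.ENOYL: frozenset({"KR", "DH"}),
    BetaState.REDUCED: frozenset({"KR", "DH", "ER"}),
}


def module_tailoring(beta_state: BetaState, alpha_methyl: bool) -> frozenset[str]:
    """Reductive/methylation domains one extension module must use.

    A beta-keto left untouched needs nothing; a beta-hydroxyl needs KR;
    an enoyl (trans double bond) needs KR then DH; a fully reduced
    methylene needs KR, DH and ER.  An alpha-methyl branch additionally
    needs the intrinsic C-methyltransferase (MT).
    """
    beta_state = BetaState(beta_state)
    if beta_state is BetaState.STARTER:
        raise ValueError("starter unit has no extension module")
    domains = _TAILORING[beta_state]
    if alpha_methyl:
        domains = domains | {"MT"}
    return domains


def decompose_chain(spec: PolyketideChainSpec) -> ChainRequirements:
    """Retro-decompose one chain into extension counts and domain demands."""
    tailoring = tuple(
        module_tailoring(u.beta_state, u.alpha_methyl)
        for u in spec.units
        if u.beta_state is not BetaState.STARTER
    )
    domains = frozenset(CORE_DOMAINS.union(*tailoring)) if tailoring else CORE_DOMAINS
    return ChainRequirements(
        chain_name=spec.name,
        units=spec.n_units,
        extensions=spec.n_units - 1,
        methyls=spec.n_methyls,
        required_domains=domains,
        per_module_tailoring=tailoring,
    )


def required_domains(req: ChainRequirements) -> frozenset[str]:
    """Full domain set a single iterative PKS needs to build the chain."""
    return req.required_domains


@dataclass(frozen=True)
class CompoundSpec:
    """A compound as a set of polyketide chains plus post-assembly steps."""

    name: str
    chains: tuple[PolyketideChainSpec, ...]
    formula: MolecularFormula
    ester_links: tuple[tuple[str, int], ...] = ()
    post_pks_hydroxylations: tuple[tuple[str, int], ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "chains", tuple(self.chains))
        object.__setattr__(self, "ester_links", tuple(self.ester_links))
        object.__setattr__(
            self, "post_pks_hydroxylations", tuple(self.post_pks_hydroxylations)
        )
        names = [c.name for c in self.chains]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chain names")

    def carbon_budget(self) -> int:
        """Backbone + alpha-methyl carbons summed over chains."""
        return sum(c.backbone_carbons + c.n_methyls for c in self.chains)


@dataclass(frozen=True)
class RetroReport:
    compound: str
    chains: tuple[ChainRequirements, ...]
    post_pks_enzymes: Mapping[str, int] = field(default_factory=dict)

    @property
    def all_required_domains(self) -> frozenset[str]:
        return frozenset().union(*(c.required_domains for c in self.chains))


def retro_compound(spec: CompoundSpec) -> RetroReport:
    """Decompose a whole compound and derive the post-PKS enzyme demands.

    Rejects specs whose chain carbons do not account for the molecular
    formula's carbon count (the acetate/methylmalonate bookkeeping must
    close before any genome scan is meaningful).
    """
    budget = spec.carbon_budget()
    n_c = spec.formula["C"]
    if budget != n_c:
        raise ValueError(
            f"carbon bookkeeping violation for {spec.name!r}: chains account for "
            f"{budget} carbons but the formula {format_formula(spec.formula)} has {n_c}"
        )
    enzymes: Counter[str] = Counter()
    if spec.ester_links:
        enzymes["O-acyltransferase"] += len(spec.ester_links)
    for chain in spec.chains:
        # An iterative PKS without a C-terminal release domain needs a
        # standalone hydrolase for hydrolytic or pyrone-forming release.
        if chain.release in (ReleaseMode.HYDROLYSIS, ReleaseMode.PYRONE_CYCLIZATION):
            enzymes["trans_thioesterase"] += 1
    enzymes["cytochrome_p450"] += len(spec.post_pks_hydroxylations)
    return RetroReport(
        compound=spec.name,
        chains=tuple(decompose_chain(c) for c in spec.chains),
        post_pks_enzymes=dict(enzymes),
    )


# ---------------------------------------------------------------------------
# Config I/O and the shipped rasfonin description
# ---------------------------------------------------------------------------


def _chain_from_config(entry: Mapping) -> PolyketideChainSpec:
    units = []
    for i, u in enumerate(entry["units"], start=1):
        units.append(
            KetideUnit(
                index=i,
                alpha_methyl=bool(u.get("alpha_methyl", False)),
                beta_state=BetaState(u.get("beta_state", "ketone")),
            )
        )
    return PolyketideChainSpec(
        name=entry["name"],
        units=tuple(units),
        release=ReleaseMode(entry["release"]),
    )


def load_compound(path) -> CompoundSpec:
    """Read a compound/chain spec from a YAML config file."""
    with open(path) as handle:
        cfg = yaml.safe_load(handle)
    return CompoundSpec(
        name=cfg["name"],
        chains=tuple(_chain_from_config(c) for c in cfg["chains"]),
        formula=parse_formula(cfg["formula"]),
        ester_links=tuple((c, int(p)) for c, p in cfg.get("ester_links", [])),
        post_pks_hydroxylations=tuple(
            (c, int(p)) for c, p in cfg.get("post_pks_hydroxylations", [])
        ),
    )


def rasfonin_hexaketide() -> PolyketideChainSpec:
    """The longer rasfonin chain: a 6,8,10-trimethylated hexaketide.

    Twelve backbone carbons (six acetate units, five malonyl extensions)
    with alpha-methyl branches at C6, C8 and C10, i.e. on extension units
    3-5 counting from the carboxyl end.  Beta-states follow the partially
    reduced alpha-pyrone-bearing chain: the C2=C3 enoyl conjugated to the
    lactone carbonyl, a C5 beta-hydroxyl that becomes the pyrone ring
    oxygen, and alternating fully reduced / enoyl positions along the
    methylated stretch.  Release is by pyrone cyclization; the PKS carries
    no release domain, implying a trans-acting thioesterase.
    """
    return PolyketideChainSpec(
        name="hexaketide",
        units=(
            KetideUnit(1, alpha_methyl=False, beta_state=BetaState.STARTER),
            KetideUnit(2, alpha_methyl=False, beta_state=BetaState.ENOYL),
            KetideUnit(3, alpha_methyl=True, beta_state=BetaState.HYDROXYL),
            KetideUnit(4, alpha_methyl=True, beta_state=BetaState.REDUCED),
            KetideUnit(5, alpha_methyl=True, beta_state=BetaState.ENOYL),
            KetideUnit(6, alpha_methyl=False, beta_state=BetaState.REDUCED),
        ),
        release=ReleaseMode.PYRONE_CYCLIZATION,
    )


def rasfonin_tetraketide() -> PolyketideChainSpec:
    """The shorter rasfonin chain: a 4',6'-dimethylated tetraketide.

    Eight backbone carbons (four acetate units, three malonyl extensions)
    with alpha-methyls on extension units 2 and 3; the C8'/C10' hydroxyls
    of the final compound are post-PKS P450 work, so the chain itself is
    built reduced/enoyl.  The chain is handed over by trans-acylation
    onto the hexaketide-derived pyrone alcohol.
    """
    return PolyketideChainSpec(
        name="tetraketide",
        units=(
            KetideUnit(1, alpha_methyl=False, beta_state=BetaState.STARTER),
            KetideUnit(2, alpha_methyl=True, beta_state=BetaState.REDUCED),
            KetideUnit(3, alpha_methyl=True, beta_state=BetaState.ENOYL),
            KetideUnit(4, alpha_methyl=False, beta_state=BetaState.REDUCED),
        ),
        release=ReleaseMode.ESTER_TRANSFER,
    )


def rasfonin_compound() -> CompoundSpec:
    """Rasfonin (C25H38O6): two ester-linked acetate-derived chains.

    2 x (6 + 4) backbone carbons + 5 alpha-methyls = 25 carbons, closing
    the bookkeeping against the molecular formula.  Post-PKS steps: ester
    linkage (O-acyltransferase), two hydroxylations on the tetraketide
    moiety (cytochrome P450s), and chain release by a standalone
    thioesterase.
    """
    return CompoundSpec(
        name="rasfonin",
        chains=(rasfonin_hexaketide(), rasfonin_tetraketide()),
        formula=parse_formula("C25H38O6"),
        ester_links=(("tetraketide", 1),),
        post_pks_hydroxylations=(("tetraketide", 8), ("tetraketide", 10)),
    )
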