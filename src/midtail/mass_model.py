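"""Monoisotopic chemistry of sortase-ligated, TMT-tagged histone H3 tails.

The analyte in this pipeline is the histone H3 N-terminal tail (residues
1-32) released by an engineered sortase, ligated to a short GGGH acceptor
peptide that carries a TMT 6-plex label on its C-terminal residue.  The
surrogate sequences searched are therefore 36 residues long::

    H3.1  ARTKQTARKSTGGKAPRKQLATKAARKSAPATGGGH
    H3.3  ARTKQTARKSTGGKAPRKQLATKAARKSAPSTGGGH

(differing only at position 31, Ala vs Ser).  A *proteoform* is one of
these base sequences plus a set of positioned variable modifications
(acetyl, the methyl series, phospho, propionyl).  This module provides:

* a residue mass table built from elemental monoisotopic masses,
* the modification registry reproducing the search-space settings
  (deltas, target residues, fixed/common/rare class, per-peptide caps),
* proteoform neutral/precursor masses,
* theoretical EThcD fragment ladders (a/b/c/y/z with neutral losses), and
* ppm error arithmetic.

All masses are monoisotopic and in daltons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import yaml

__all__ = [
    "ATOMIC_MASS",
    "RESIDUE_COMPOSITIONS",
    "PROTON_MASS",
    "WATER_MASS",
    "C13_C12_SPACING",
    "H3_SEQUENCES",
    "SHORT_MOD_CODES",
    "UnknownResidueError",
    "UnknownModificationError",
    "ProteoformError",
    "ResidueTable",
    "ModificationDelta",
    "Proteoform",
    "FragmentIon",
    "composition_mass",
    "residue_mass",
    "default_modification_registry",
    "load_modification_registry",
    "save_modification_registry",
    "modification_delta",
    "proteoform_neutral_mass",
    "precursor_mz",
    "fragment_ladder",
    "ppm_error",
]

# ---------------------------------------------------------------------------
# Elemental constants (IUPAC/CODATA monoisotopic atomic masses, Da)
# ---------------------------------------------------------------------------

ATOMIC_MASS: dict[str, float] = {
    "H": 1.00782503207,
    "C": 12.0,
    "C13": 13.0033548378,
    "N": 14.0030740048,
    "N15": 15.0001088982,
    "O": 15.9949146196,
    "P": 30.97376163,
    "S": 31.97207100,
}

PROTON_MASS = 1.007276466  # mass of H+ (hydrogen atom minus electron)
C13_C12_SPACING = 1.0033548378  # heavy-isotope peak spacing at charge 1

# Elemental compositions of the 20 canonical amino acid residues
# (the residue, i.e. amino acid minus water).
RESIDUE_COMPOSITIONS: dict[str, dict[str, int]] = {
    "G": {"C": 2, "H": 3, "N": 1, "O": 1},
    "A": {"C": 3, "H": 5, "N": 1, "O": 1},
    "S": {"C": 3, "H": 5, "N": 1, "O": 2},
    "P": {"C": 5, "H": 7, "N": 1, "O": 1},
    "V": {"C": 5, "H": 9, "N": 1, "O": 1},
    "T": {"C": 4, "H": 7, "N": 1, "O": 2},
    "C": {"C": 3, "H": 5, "N": 1, "O": 1, "S": 1},
    "L": {"C": 6, "H": 11, "N": 1, "O": 1},
    "I": {"C": 6, "H": 11, "N": 1, "O": 1},
    "N": {"C": 4, "H": 6, "N": 2, "O": 2},
    "D": {"C": 4, "H": 5, "N": 1, "O": 3},
    "Q": {"C": 5, "H": 8, "N": 2, "O": 2},
    "K": {"C": 6, "H": 12, "N": 2, "O": 1},
    "E": {"C": 5, "H": 7, "N": 1, "O": 3},
    "M": {"C": 5, "H": 9, "N": 1, "O": 1, "S": 1},
    "H": {"C": 6, "H": 7, "N": 3, "O": 1},
    "F": {"C": 9, "H": 9, "N": 1, "O": 1},
    "R": {"C": 6, "H": 12, "N": 4, "O": 1},
    "Y": {"C": 9, "H": 9, "N": 1, "O": 2},
    "W": {"C": 11, "H": 10, "N": 2, "O": 1},
}


def composition_mass(composition: Mapping[str, int | float]) -> float:
    """Monoisotopic mass of an elemental composition, e.g. ``{"C": 2, "H": 2, "O": 1}``."""
    return sum(ATOMIC_MASS[el] * n for el, n in composition.items())


WATER_MASS = composition_mass({"H": 2, "O": 1})
_NH3_MASS = composition_mass({"N": 1, "H": 3})
_CO_MASS = composition_mass({"C": 1, "O": 1})
_NH2_MASS = composition_mass({"N": 1, "H": 2})
_H_MASS = ATOMIC_MASS["H"]
PHOSPHO_NEUTRAL_LOSS = composition_mass({"H": 3, "P": 1, "O": 4})  # H3PO4, 97.9769

#: Neutral-loss name -> mass subtracted from the fragment's neutral mass.
NEUTRAL_LOSS_MASS: dict[str, float] = {
    "none": 0.0,
    "NH3": _NH3_MASS,
    "H2O": WATER_MASS,
    "H3PO4": PHOSPHO_NEUTRAL_LOSS,
}

_SERIES_ORDER = {"a": 0, "b": 1, "c": 2, "y": 3, "z": 4}

H3_SEQUENCES: dict[str, str] = {
    "H3.1": "ARTKQTARKSTGGKAPRKQLATKAARKSAPATGGGH",
    "H3.3": "ARTKQTARKSTGGKAPRKQLATKAARKSAPSTGGGH",
}

#: Canonical short codes used in proteoform ids (e.g. H3.1K9acK14ac).
SHORT_MOD_CODES: dict[str, str] = {
    "Methyl": "me1",
    "Dimethyl": "me2",
    "Trimethyl": "me3",
    "Acetyl": "ac",
    "Phospho": "ph",
    "Propionyl": "pr",
}

C_TERM = "protein-C-term"
N_TERM = "protein-N-term"

# Per-peptide totals over all variable mods of a class.
MAX_TOTAL_COMMON = 6
MAX_TOTAL_RARE = 1


class UnknownResidueError(KeyError):
    """Raised for residue codes outside the 20 canonical amino acids."""


class UnknownModificationError(KeyError):
    """Raised for modification names absent from the registry."""


class ProteoformError(ValueError):
    """Raised when a proteoform violates the search-space constraints."""


# ---------------------------------------------------------------------------
# Residue table
# ---------------------------------------------------------------------------


def _default_residue_masses() -> dict[str, float]:
    return {aa: composition_mass(c) for aa, c in RESIDUE_COMPOSITIONS.items()}


@dataclass(frozen=True)
class ResidueTable:
    """Monoisotopic residue masses plus the scalar constants of the mass scale."""

    masses: Mapping[str, float] = field(default_factory=_default_residue_masses)
    water_mass: float = WATER_MASS
    proton_mass: float = PROTON_MASS
    c13_c12_spacing: float = C13_C12_SPACING

    def residue_mass(self, code: str) -> float:
        try:
            return self.masses[code]
        except KeyError:
            raise UnknownResidueError(
                f"unknown residue code {code!r}; expected one of the 20 canonical amino acids"
            ) from None


_DEFAULT_TABLE = ResidueTable()


def residue_mass(code: str, table: ResidueTable = _DEFAULT_TABLE) -> float:
    """Monoisotopic residue mass (Da) of a canonical single-letter amino acid code."""
    return table.residue_mass(code)


# ---------------------------------------------------------------------------
# Modification registry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModificationDelta:
    """A named monoisotopic mass shift with its search-space constraints.

    ``mod_class`` is ``"fixed"`` (applied to every matching site, no cap),
    ``"common"`` or ``"rare"``; ``max_count`` is the per-peptide occurrence
    cap for variable mods and ``None`` for fixed ones.
    """

    name: str
    delta: float
    targets: frozenset[str]
    mod_class: str
    max_count: int | None = None

    def __post_init__(self) -> None:
        if self.mod_class not in ("fixed", "common", "rare"):
            raise ValueError(f"bad mod_class {self.mod_class!r}")
        if self.mod_class == "fixed" and self.max_count is not None:
            raise ValueError("fixed modifications carry no occurrence cap")


def default_modification_registry() -> dict[str, ModificationDelta]:
    """The search-space modification set for TMT-tagged H3 tails.

    Variable deltas are computed from elemental compositions; the TMT 6-plex
    label includes its four 13C and one 15N heavy isotopes.  The C-terminal
    ligation offset (+76.1001 Da) is the empirical mass difference between
    the genome-encoded continuation of H3 and the ligated
    K(2,3-diaminopropionamide) acceptor and is kept as configured.
    """
    mk = composition_mass
    mods = [
        ModificationDelta("Methyl", mk({"C": 1, "H": 2}), frozenset("KR"), "common", 3),
        ModificationDelta("Dimethyl", mk({"C": 2, "H": 4}), frozenset("KR"), "common", 3),
        ModificationDelta("Trimethyl", mk({"C": 3, "H": 6}), frozenset("K"), "common", 3),
        ModificationDelta("Phospho", mk({"H": 1, "P": 1, "O": 3}), frozenset("ST"), "common", 2),
        ModificationDelta("Acetyl", mk({"C": 2, "H": 2, "O": 1}), frozenset("K"), "common", 5),
        ModificationDelta("Propionyl", mk({"C": 3, "H": 4, "O": 1}), frozenset("K"), "rare", 1),
        ModificationDelta(
            "TMT6plex",
            mk({"C": 8, "C13": 4, "H": 20, "N": 1, "N15": 1, "O": 2}),
            frozenset("H"),
            "fixed",
        ),
        ModificationDelta("CtermLigationOffset", 76.1001, frozenset({C_TERM}), "fixed"),
    ]
    return {m.name: m for m in mods}


def modification_delta(
    name: str, registry: Mapping[str, ModificationDelta] | None = None
) -> ModificationDelta:
    """Look up a registered modification by name."""
    registry = registry if registry is not None else default_modification_registry()
    try:
        return registry[name]
    except KeyError:
        raise UnknownModificationError(
            f"modification {name!r} is not in the registry "
            f"(known: {sorted(registry)})"
        ) from None


def save_modification_registry(registry: Mapping[str, ModificationDelta], path) -> None:
    data = {
        name: {
            "delta": m.delta,
            "targets": sorted(m.targets),
            "mod_class": m.mod_class,
            "max_count": m.max_count,
        }
        for name, m in registry.items()
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


def load_modification_registry(path) -> dict[str, ModificationDelta]:
    """Load a user registry from YAML (same schema ``save_modification_registry`` writes)."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    out = {}
    for name, d in data.items():
        out[name] = ModificationDelta(
            name=name,
            delta=float(d["delta"]),
            targets=frozenset(d["targets"]),
            mod_class=d["mod_class"],
            max_count=d.get("max_count"),
        )
    return out


# ---------------------------------------------------------------------------
# Proteoforms
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Proteoform:
    """A base tail sequence plus positioned variable modifications.

    ``mods`` is a tuple of ``(position, modification name)`` with 1-based
    positions in standard H3 coordinates on the surrogate sequence.
    """

    base_id: str
    mods: tuple[tuple[int, str], ...] = ()
    sequence: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            if self.base_id not in H3_SEQUENCES:
                raise ProteoformError(
                    f"unknown base_id {self.base_id!r} and no explicit sequence given"
                )
            object.__setattr__(self, "sequence", H3_SEQUENCES[self.base_id])
        # normalize mod order so equality/hashing is order-insensitive
        object.__setattr__(
            self, "mods", tuple(sorted(self.mods, key=lambda m: (m[0], m[1])))
        )

    def validate(self, registry: Mapping[str, ModificationDelta] | None = None) -> None:
        """Check the search-space invariants; raise :class:`ProteoformError` if violated."""
        registry = registry if registry is not None else default_modification_registry()
        seen_positions: set[int] = set()
        per_mod: dict[str, int] = {}
        per_class = {"common": 0, "rare": 0}
        for pos, name in self.mods:
            mod = modification_delta(name, registry)
            if mod.mod_class == "fixed":
                raise ProteoformError(f"fixed mod {name!r} may not be listed as variable")
            if not 1 <= pos <= len(self.sequence):
                raise ProteoformError(f"position {pos} outside sequence of length {len(self.sequence)}")
            if pos in seen_positions:
                raise ProteoformError(f"position {pos} carries more than one modification")
            seen_positions.add(pos)
            res = self.sequence[pos - 1]
            if res not in mod.targets:
                raise ProteoformError(
                    f"{name} targets {sorted(mod.targets)} but position {pos} is {res!r}"
                )
            per_mod[name] = per_mod.get(name, 0) + 1
            per_class[mod.mod_class] += 1
            if mod.max_count is not None and per_mod[name] > mod.max_count:
                raise ProteoformError(f"more than {mod.max_count} {name} modifications")
        if per_class["common"] > MAX_TOTAL_COMMON:
            raise ProteoformError(f"more than {MAX_TOTAL_COMMON} common modifications")
        if per_class["rare"] > MAX_TOTAL_RARE:
            raise ProteoformError(f"more than {MAX_TOTAL_RARE} rare modifications")

    @property
    def canonical_id(self) -> str:
        """Canonical text id, e.g. ``H3.1K9acK14acK23acK27me2``."""
        parts = [self.base_id]
        for pos, name in self.mods:
            code = SHORT_MOD_CODES.get(name, name.lower())
            parts.append(f"{self.sequence[pos - 1]}{pos}{code}")
        return "".join(parts)

    def with_mod(self, pos: int, name: str) -> "Proteoform":
        return replace(self, mods=self.mods + ((pos, name),))

    def without_mod(self, pos: int, name: str) -> "Proteoform":
        mods = list(self.mods)
        mods.remove((pos, name))
        return replace(self, mods=tuple(mods))


def _per_position_masses(
    p: Proteoform,
    registry: Mapping[str, ModificationDelta],
    table: ResidueTable,
) -> list[float]:
    """Residue + fixed + variable modification mass at each position (0-based list)."""
    masses = [table.residue_mass(aa) for aa in p.sequence]
    for i, aa in enumerate(p.sequence):
        for mod in registry.values():
            if mod.mod_class == "fixed" and aa in mod.targets:
                masses[i] += mod.delta
    for pos, name in p.mods:
        masses[pos - 1] += modification_delta(name, registry).delta
    return masses


def _cterm_fixed_offset(registry: Mapping[str, ModificationDelta]) -> float:
    return sum(
        m.delta for m in registry.values() if m.mod_class == "fixed" and C_TERM in m.targets
    )


def proteoform_neutral_mass(
    p: Proteoform,
    registry: Mapping[str, ModificationDelta] | None = None,
    table: ResidueTable = _DEFAULT_TABLE,
) -> float:
    """Monoisotopic neutral mass of a proteoform.

    Sum of residue masses + water + every fixed modification (TMT on each
    His, the C-terminal ligation offset) + the variable modification deltas.
    """
    registry = registry if registry is not None else default_modification_registry()
    p.validate(registry)
    return (
        sum(_per_position_masses(p, registry, table))
        + table.water_mass
        + _cterm_fixed_offset(registry)
    )


def precursor_mz(
    p: Proteoform,
    charge: int,
    registry: Mapping[str, ModificationDelta] | None = None,
    table: ResidueTable = _DEFAULT_TABLE,
) -> float:
    """m/z of the protonated precursor at the given charge state."""
    if charge < 1:
        raise ValueError("charge must be >= 1")
    neutral = proteoform_neutral_mass(p, registry, table)
    return (neutral + charge * table.proton_mass) / charge


# ---------------------------------------------------------------------------
# Fragment ladders
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FragmentIon:
    """One theoretical EThcD fragment: series, cleavage index, charge, loss, m/z."""

    series: str
    index: int
    charge: int
    neutral_loss: str
    theoretical_mz: float
    neutral_mass: float

    @property
    def label(self) -> str:
        loss = "" if self.neutral_loss == "none" else f"-{self.neutral_loss}"
        return f"{self.series}{self.index}{loss}^{self.charge}"

    def sort_key(self) -> tuple[int, int, int]:
        """Deterministic tie-break order: index, then a<b<c<y<z, then charge."""
        return (self.index, _SERIES_ORDER[self.series], self.charge)


def fragment_ladder(
    p: Proteoform,
    max_charge: int = 1,
    losses: Iterable[str] = ("none", "NH3", "H2O"),
    series: Sequence[str] = ("a", "b", "c", "y", "z"),
    registry: Mapping[str, ModificationDelta] | None = None,
    table: ResidueTable = _DEFAULT_TABLE,
    z_radical: bool = True,
) -> list[FragmentIon]:
    """All theoretical a/b/c/y/z fragments of a proteoform.

    N-terminal series (a/b/c) carry the modifications located N-terminal of
    the cleavage site; C-terminal series (y/z) carry the rest plus the
    C-terminal fixed ligation offset.  Conventions (neutral masses)::

        b_i = sum(res 1..i)            a_i = b_i - CO      c_i = b_i + NH3
        y_j = sum(res n-j+1..n) + H2O + C-term offset
        z_j = y_j - NH2                (z-dot radical; plain z = z-dot - H)

    and ``m/z = (neutral - loss + charge * proton) / charge``.
    """
    if not p.sequence:
        raise ProteoformError("empty peptide")
    if max_charge < 1:
        raise ValueError("max_charge must be >= 1")
    registry = registry if registry is not None else default_modification_registry()
    p.validate(registry)

    pos_masses = _per_position_masses(p, registry, table)
    n = len(pos_masses)
    cterm = _cterm_fixed_offset(registry)

    prefix = [0.0]
    for m in pos_masses:
        prefix.append(prefix[-1] + m)
    total = prefix[-1]

    z_offset = _NH2_MASS if z_radical else _NH2_MASS + _H_MASS

    out: list[FragmentIon] = []
    for i in range(1, n):  # cleavage after residue i; index < peptide length
        b = prefix[i]
        y = (total - prefix[n - i]) + table.water_mass + cterm
        neutral_by_series = {
            "a": b - _CO_MASS,
            "b": b,
            "c": b + _NH3_MASS,
            "y": y,
            "z": y - z_offset,
        }
        for s in series:
            neutral = neutral_by_series[s]
            for loss in losses:
                nm = neutral - NEUTRAL_LOSS_MASS[loss]
                if nm <= 0:
                    continue
                for ch in range(1, max_charge + 1):
                    out.append(
                        FragmentIon(
                            series=s,
                            index=i,
                            charge=ch,
                            neutral_loss=loss,
                            theoretical_mz=(nm + ch * table.proton_mass) / ch,
                            neutral_mass=nm,
                        )
                    )
    return out


def ppm_error(theoretical: float, observed: float) -> float:
    """Signed mass error in parts per million: ``1e6 * (obs - theo) / theo``."""
    if theoretical <= 0:
        raise ValueError("theoretical mass must be > 0")
    return 1e6 * (observed - theoretical) / theoretical


def within_ppm(theoretical: float, observed: float, tol_ppm: float) -> bool:
    return abs(ppm_error(theoretical, observed)) <= tol_ppm
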