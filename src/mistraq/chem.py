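"""Monoisotopic mass arithmetic for residues, modifications and substitutions.

Amino-acid misincorporation shows up in a shotgun-proteomics search as a
variable modification whose delta mass is the difference between the
misincorporated and the encoded residue (e.g. Pro->Ser is -10.0207 Da).
This module computes those deltas from elemental residue masses, combines
them with conventional PTMs (phosphorylation of a misinserted serine is the
substitution delta plus +79.9663 Da), and assembles the full
variable-modification table a search engine would need for a given
mistranslating strain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Tuple

import yaml
from pyteomics import mass as _pmass

from .codons import GENETIC_CODE, codon_family

STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Monoisotopic residue (not free amino acid) masses in Da.
RESIDUE_MASSES: dict[str, float] = {
    aa: _pmass.std_aa_mass[aa] for aa in STANDARD_RESIDUES
}

#: Monoisotopic mass of water; added once per peptide for the neutral mass.
WATER_MASS: float = _pmass.calculate_mass(formula="H2O")


def residue_mass(residue: str) -> float:
    """Monoisotopic residue mass in Da for a one-letter amino-acid code."""
    try:
        return RESIDUE_MASSES[residue]
    except KeyError:
        raise ValueError(f"unknown amino-acid code: {residue!r}") from None


@dataclass(frozen=True)
class ModificationSpec:
    """A named variable (or fixed) modification.

    ``targets`` is the set of residues the modification may sit on;
    ``protein_nterm`` marks protein N-terminal modifications, which carry an
    empty target set.
    """

    name: str
    delta: float
    targets: frozenset = frozenset()
    protein_nterm: bool = False

    def applies_to(self, residue: str) -> bool:
        return residue in self.targets


PHOSPHO = ModificationSpec(
    "Phospho", _pmass.calculate_mass(formula="HPO3"), frozenset("STY")
)
OXIDATION = ModificationSpec(
    "Oxidation", _pmass.calculate_mass(formula="O"), frozenset("M")
)
NTERM_ACETYL = ModificationSpec(
    "Acetyl", _pmass.calculate_mass(formula="C2H2O"), protein_nterm=True
)
# Alkylation with iodoacetamide is routine in sample preparation, but it is
# off by default here; enable explicitly where the search used it as a fixed
# modification.
CARBAMIDOMETHYL = ModificationSpec(
    "Carbamidomethyl", _pmass.calculate_mass(formula="C2H3NO"), frozenset("C")
)

NAMED_MODIFICATIONS = {
    m.name: m for m in (PHOSPHO, OXIDATION, NTERM_ACETYL, CARBAMIDOMETHYL)
}


def substitution_delta(from_residue: str, to_residue: str) -> float:
    """Mass delta (Da) of replacing ``from_residue`` with ``to_residue``."""
    return residue_mass(to_residue) - residue_mass(from_residue)


def combined_delta(
    from_residue: str, to_residue: str, modification: ModificationSpec
) -> float:
    """Delta of a substitution plus a PTM on the misinserted residue.

    The modification must be applicable to the *destination* residue: a
    phosphate can ride on a misinserted serine but not on a misinserted
    alanine.
    """
    if not modification.applies_to(to_residue):
        raise ValueError(
            f"modification {modification.name} does not target {to_residue!r}"
        )
    return substitution_delta(from_residue, to_residue) + modification.delta


@dataclass(frozen=True)
class SubstitutionSpec:
    """One strain's amino-acid substitution and the codons it decodes.

    ``target_codons`` are the codons the mutant tRNA can read; they must all
    encode ``from_residue`` in the standard genetic code.  ``delta`` is
    always derived from residue masses, never supplied.
    """

    from_residue: str
    to_residue: str
    target_codons: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        residue_mass(self.from_residue)
        residue_mass(self.to_residue)
        codons = frozenset(c.upper() for c in self.target_codons)
        if not codons:
            codons = codon_family(self.from_residue)
        for codon in codons:
            if GENETIC_CODE.get(codon) != self.from_residue:
                raise ValueError(
                    f"codon {codon} does not encode {self.from_residue!r}"
                )
        object.__setattr__(self, "target_codons", codons)

    @property
    def delta(self) -> float:
        return substitution_delta(self.from_residue, self.to_residue)

    @property
    def codon_family(self) -> frozenset:
        """All codons of the from-residue (profile denominator)."""
        return codon_family(self.from_residue)

    @property
    def is_identity(self) -> bool:
        return self.from_residue == self.to_residue

    @property
    def name(self) -> str:
        return f"{self.from_residue}->{self.to_residue}"


# The three substitutions studied: an alanine tRNA charged at proline codons
# and two serine tRNAs with proline (UGG) or arginine (UCU) anticodons.  The
# UCU serine tRNA reads AGA by Watson-Crick pairing and AGG by wobble.
PRO_TO_ALA = SubstitutionSpec("P", "A")
PRO_TO_SER = SubstitutionSpec("P", "S")
ARG_TO_SER = SubstitutionSpec("R", "S", frozenset({"AGA", "AGG"}))

STRAIN_SUBSTITUTIONS = {
    "pro_to_ala": PRO_TO_ALA,
    "pro_to_ser": PRO_TO_SER,
    "arg_to_ser": ARG_TO_SER,
}


def build_search_mod_table(
    spec: SubstitutionSpec,
    include_phospho: bool = False,
    fixed_carbamidomethyl: bool = False,
) -> list[ModificationSpec]:
    """Variable-modification list for searching one strain's data.

    Always contains methionine oxidation and protein N-terminal acetylation;
    adds the substitution delta on the from-residue, and, when
    ``include_phospho`` is set, STY phosphorylation plus the combined
    substitution+phospho delta (only when the destination residue is
    phosphorylatable).
    """
    mods: list[ModificationSpec] = [OXIDATION, NTERM_ACETYL]
    if fixed_carbamidomethyl:
        mods.append(CARBAMIDOMETHYL)
    if not spec.is_identity:
        mods.append(
            ModificationSpec(
                spec.name, spec.delta, frozenset({spec.from_residue})
            )
        )
    if include_phospho:
        mods.append(PHOSPHO)
        if not spec.is_identity and PHOSPHO.applies_to(spec.to_residue):
            mods.append(
                ModificationSpec(
                    f"{spec.name}+Phospho",
                    combined_delta(spec.from_residue, spec.to_residue, PHOSPHO),
                    frozenset({spec.from_residue}),
                )
            )
    return mods


def peptide_neutral_mass(
    sequence: str,
    modifications: Iterable[Tuple[int, ModificationSpec]] = (),
) -> float:
    """Neutral monoisotopic mass of a peptide with applied modifications.

    ``modifications`` is an iterable of ``(position, spec)`` with 1-based
    positions inside the peptide.  The result does not depend on the order
    modifications are listed.
    """
    total = WATER_MASS
    for aa in sequence:
        total += residue_mass(aa)
    n = len(sequence)
    for pos, mod in modifications:
        if not 1 <= pos <= n:
            raise ValueError(
                f"modification site {pos} outside peptide of length {n}"
            )
        if mod.targets and sequence[pos - 1] not in mod.targets:
            raise ValueError(
                f"{mod.name} cannot sit on {sequence[pos - 1]!r} at {pos}"
            )
        if mod.protein_nterm and pos != 1:
            raise ValueError(f"{mod.name} is N-terminal; got position {pos}")
        total += mod.delta
    return total


def mod_table_to_tsv(mods: Sequence[ModificationSpec]) -> str:
    """Serialize a modification table as TSV (name, delta_da, targets, terminus)."""
    lines = ["name\tdelta_da\ttargets\tterminus"]
    for m in mods:
        targets = "".join(sorted(m.targets)) if m.targets else "-"
        terminus = "protein_n" if m.protein_nterm else "-"
        lines.append(f"{m.name}\t{m.delta:.5f}\t{targets}\t{terminus}")
    return "\n".join(lines) + "\n"


def mod_table_to_yaml(mods: Sequence[ModificationSpec]) -> str:
    """Serialize a modification table as a YAML config block."""
    block = {
        "variable_modifications": [
            {
                "name": m.name,
                "delta_da": round(m.delta, 5),
                "targets": "".join(sorted(m.targets)) if m.targets else None,
                "terminus": "protein_n" if m.protein_nterm else None,
            }
            for m in mods
        ]
    }
    return yaml.safe_dump(block, sort_keys=False)
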