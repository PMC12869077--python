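"""In-silico protease digestion, substitution-aware.

Beyond plain digestion this module enumerates the theoretical peptide space
of a mistranslating strain: a substitution can create a cleavage site (a
misinserted K/R) or destroy one (R->S under trypsin), so substituted
peptides are obtained by digesting the *mutated* protein, not by editing
wild-type peptides.  The sibling of a substituted peptide is the wild-type
peptide with identical coordinates, when the wild-type digest produces one.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Tuple

from .chem import STANDARD_RESIDUES, SubstitutionSpec

#: Default peptide length window and missed-cleavage bound, matching common
#: search-engine defaults; both are configurable at every call site.
DEFAULT_LENGTH_RANGE: Tuple[int, int] = (7, 50)
DEFAULT_MAX_MISSED = 2


@dataclass(frozen=True)
class ProteaseRule:
    """Cleave after any residue in ``cleave_after`` unless the next residue
    is in ``blocked_by_next`` (the Keil rule for trypsin)."""

    name: str
    cleave_after: frozenset
    blocked_by_next: frozenset = frozenset()

    def cleavage_sites(self, sequence: str) -> list[int]:
        """0-based indices i such that the bond after residue i is cut."""
        return [
            i
            for i in range(len(sequence) - 1)
            if sequence[i] in self.cleave_after
            and sequence[i + 1] not in self.blocked_by_next
        ]


@dataclass(frozen=True)
class CompositeRule:
    """Union of protease rules: a bond is cut if any member cuts it."""

    name: str
    rules: Tuple[ProteaseRule, ...]

    def cleavage_sites(self, sequence: str) -> list[int]:
        sites: set = set()
        for rule in self.rules:
            sites.update(rule.cleavage_sites(sequence))
        return sorted(sites)


TRYPSIN = ProteaseRule("trypsin", frozenset("KR"), frozenset("P"))
LYSC = ProteaseRule("lysc", frozenset("K"))
# In a trypsin+LysC double digest LysC still cuts K-P bonds.
TRYPSIN_LYSC = CompositeRule("trypsin+lysc", (TRYPSIN, LYSC))

PROTEASES = {r.name: r for r in (TRYPSIN, LYSC, TRYPSIN_LYSC)}


@dataclass(frozen=True)
class SubstitutionSite:
    """A single residue replacement at a 1-based protein position."""

    position: int
    from_residue: str
    to_residue: str


@dataclass(frozen=True)
class TheoreticalPeptide:
    sequence: str
    protein_id: str
    start: int  # 1-based inclusive protein coordinates
    end: int
    missed_cleavages: int
    substitution_sites: Tuple[SubstitutionSite, ...] = ()

    def __post_init__(self):
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError("coordinates inconsistent with sequence length")
        for site in self.substitution_sites:
            if not self.start <= site.position <= self.end:
                raise ValueError("substitution site outside peptide")

    def covers(self, position: int) -> bool:
        return self.start <= position <= self.end


def _check_sequence(sequence: str) -> None:
    if not sequence:
        raise ValueError("empty protein sequence")
    bad = set(sequence) - STANDARD_RESIDUES
    if bad:
        raise ValueError(f"invalid residues in sequence: {sorted(bad)}")


def digest(
    protein_sequence: str,
    rule=TRYPSIN,
    max_missed: int = DEFAULT_MAX_MISSED,
    length_range: Optional[Tuple[int, int]] = DEFAULT_LENGTH_RANGE,
    protein_id: str = "",
) -> list[TheoreticalPeptide]:
    """Fully specific digest with up to ``max_missed`` missed cleavages.

    With ``max_missed=0`` and ``length_range=None`` the products tile the
    protein exactly.  Coordinates are 1-based inclusive.
    """
    _check_sequence(protein_sequence)
    sites = rule.cleavage_sites(protein_sequence)
    bounds = [0] + [i + 1 for i in sites] + [len(protein_sequence)]
    peptides: list[TheoreticalPeptide] = []
    for i in range(len(bounds) - 1):
        for j in range(i + 1, min(i + 2 + max_missed, len(bounds))):
            start, end = bounds[i], bounds[j]
            length = end - start
            if length_range is not None and not (
                length_range[0] <= length <= length_range[1]
            ):
                continue
            peptides.append(
                TheoreticalPeptide(
                    sequence=protein_sequence[start:end],
                    protein_id=protein_id,
                    start=start + 1,
                    end=end,
                    missed_cleavages=j - i - 1,
                )
            )
    return peptides


def _apply_substitutions(sequence: str, sites: Sequence[SubstitutionSite]) -> str:
    chars = list(sequence)
    for site in sites:
        if chars[site.position - 1] != site.from_residue:
            raise ValueError(
                f"residue at {site.position} is {chars[site.position - 1]!r},"
                f" not {site.from_residue!r}"
            )
        chars[site.position - 1] = site.to_residue
    return "".join(chars)


def enumerate_substituted_peptides(
    protein_sequence: str,
    spec: SubstitutionSpec,
    rule=TRYPSIN,
    max_missed: int = DEFAULT_MAX_MISSED,
    length_range: Optional[Tuple[int, int]] = DEFAULT_LENGTH_RANGE,
    max_subs_per_peptide: int = 1,
    protein_id: str = "",
) -> set[TheoreticalPeptide]:
    """All theoretical peptides carrying the strain's substitution.

    Each combination of from-residue positions (up to
    ``max_subs_per_peptide``, all of which must fit inside one peptide) is
    applied to the protein; the mutated protein is digested and peptides
    covering every substituted position are kept.  Boundaries therefore
    reflect cleavage sites created or destroyed by the substitution.
    """
    _check_sequence(protein_sequence)
    positions = [
        i + 1
        for i, aa in enumerate(protein_sequence)
        if aa == spec.from_residue
    ]
    max_span = (
        length_range[1] if length_range is not None else len(protein_sequence)
    )
    out: set[TheoreticalPeptide] = set()
    for k in range(1, max_subs_per_peptide + 1):
        for combo in itertools.combinations(positions, k):
            if combo[-1] - combo[0] >= max_span:
                continue
            sites = tuple(
                SubstitutionSite(p, spec.from_residue, spec.to_residue)
                for p in combo
            )
            mutated = _apply_substitutions(protein_sequence, sites)
            for pep in digest(
                mutated, rule, max_missed, length_range, protein_id
            ):
                if all(pep.covers(p) for p in combo):
                    out.add(
                        TheoreticalPeptide(
                            sequence=pep.sequence,
                            protein_id=protein_id,
                            start=pep.start,
                            end=pep.end,
                            missed_cleavages=pep.missed_cleavages,
                            substitution_sites=sites,
                        )
                    )
    return out


def sibling_of(
    peptide: TheoreticalPeptide,
    proteome: Mapping[str, str],
    rule=TRYPSIN,
    max_missed: int = DEFAULT_MAX_MISSED,
    length_range: Optional[Tuple[int, int]] = DEFAULT_LENGTH_RANGE,
) -> Optional[TheoreticalPeptide]:
    """Wild-type peptide with the same coordinates, or None.

    None means the substitution changed the cleavage pattern such that no
    coordinate-identical wild-type peptide exists; such substituted peptides
    cannot be sibling-validated under this protease.
    """
    if not peptide.substitution_sites:
        raise ValueError("peptide carries no substitution")
    if all(
        s.from_residue == s.to_residue for s in peptide.substitution_sites
    ):
        return peptide
    wild = proteome[peptide.protein_id]
    for pep in digest(wild, rule, max_missed, length_range, peptide.protein_id):
        if (pep.start, pep.end) == (peptide.start, peptide.end):
            return pep
    return None
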