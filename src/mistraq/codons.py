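"""CDS handling and per-codon attribution of misincorporation events.

A misincorporated residue is attributed to the codon that encoded the
original residue, read off the gene's coding sequence.  Aggregating accepted
substituted peptides by encoding codon yields a codon profile: how much of
the misincorporation each synonymous codon carries.  For an anticodon-mutant
tRNA the expectation is strong enrichment at the codon(s) the mutant
anticodon can read, with the Watson-Crick partner dominating.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Mapping, Optional

import pandas as pd
from Bio.Data import CodonTable

if TYPE_CHECKING:  # pragma: no cover
    from .chem import SubstitutionSpec

_TABLE = CodonTable.unambiguous_dna_by_id[1]

#: Standard nuclear genetic code, codon -> one-letter residue (stops absent).
GENETIC_CODE: dict[str, str] = dict(_TABLE.forward_table)

STOP_CODONS = frozenset(_TABLE.stop_codons)


def codon_family(residue: str) -> frozenset:
    """All codons encoding ``residue`` under the standard genetic code."""
    fam = frozenset(c for c, aa in GENETIC_CODE.items() if aa == residue)
    if not fam:
        raise ValueError(f"no codons encode {residue!r}")
    return fam


@dataclass(frozen=True)
class CdsRecord:
    """A gene's spliced coding sequence paired with its protein product."""

    gene_id: str
    cds: str
    protein: str


def validate_cds(record: CdsRecord) -> CdsRecord:
    """Check that the CDS translates exactly to the protein.

    The CDS may optionally end with a stop codon; internal stops, length
    mismatches and translation mismatches are rejected, naming the 1-based
    protein position of the first offending codon.
    """
    cds = record.cds.upper()
    if set(cds) - set("ACGT"):
        bad = sorted(set(cds) - set("ACGT"))
        raise ValueError(f"{record.gene_id}: non-ACGT characters {bad}")
    if len(cds) % 3 != 0:
        raise ValueError(
            f"{record.gene_id}: CDS length {len(cds)} not divisible by 3"
        )
    n_codons = len(cds) // 3
    n_res = len(record.protein)
    if n_codons not in (n_res, n_res + 1):
        raise ValueError(
            f"{record.gene_id}: {n_codons} codons for {n_res} residues"
        )
    for i in range(n_res):
        codon = cds[3 * i : 3 * i + 3]
        aa = GENETIC_CODE.get(codon)
        if aa is None:
            raise ValueError(
                f"{record.gene_id}: internal stop codon at position {i + 1}"
            )
        if aa != record.protein[i]:
            raise ValueError(
                f"{record.gene_id}: translation mismatch at position {i + 1}"
                f" ({codon} -> {aa}, protein has {record.protein[i]})"
            )
    if n_codons == n_res + 1 and cds[-3:] not in STOP_CODONS:
        raise ValueError(
            f"{record.gene_id}: trailing codon {cds[-3:]} is not a stop"
        )
    return record


def residue_codon(record: CdsRecord, protein_position: int) -> str:
    """Codon encoding the residue at a 1-based protein position."""
    if not 1 <= protein_position <= len(record.protein):
        raise ValueError(
            f"{record.gene_id}: position {protein_position} outside protein"
            f" of length {len(record.protein)}"
        )
    i = 3 * (protein_position - 1)
    return record.cds[i : i + 3].upper()


@dataclass
class CodonProfile:
    """Per-codon misincorporation counts, intensities and frequencies.

    Counts are unique substituted peptides; intensities are summed over all
    matches.  Frequencies are normalized over the from-residue's full codon
    family; both count-based and intensity-based normalizations are exposed
    because either may be wanted downstream.
    """

    from_residue: str
    counts: dict = field(default_factory=dict)
    intensity: dict = field(default_factory=dict)
    ambiguous: list = field(default_factory=list)
    rejected: list = field(default_factory=list)

    @property
    def total_count(self) -> int:
        return sum(self.counts.values())

    def count_frequency(self) -> Optional[dict]:
        total = self.total_count
        if total == 0:
            return None
        return {c: n / total for c, n in self.counts.items()}

    def intensity_frequency(self) -> Optional[dict]:
        total = sum(self.intensity.values())
        if total <= 0:
            return None
        return {c: v / total for c, v in self.intensity.items()}

    def to_frame(self) -> pd.DataFrame:
        freq = self.count_frequency() or {}
        ifreq = self.intensity_frequency() or {}
        codons = sorted(self.counts)
        return pd.DataFrame(
            {
                "codon": codons,
                "count": [self.counts[c] for c in codons],
                "intensity_sum": [self.intensity[c] for c in codons],
                "frequency": [freq.get(c, float("nan")) for c in codons],
                "intensity_frequency": [
                    ifreq.get(c, float("nan")) for c in codons
                ],
            }
        )


def codon_profile(
    matches: pd.DataFrame,
    cds_index: Mapping[str, CdsRecord],
    spec: "SubstitutionSpec",
) -> CodonProfile:
    """Attribute accepted substituted peptides to their encoding codons.

    ``matches`` is a report frame (see :mod:`mistraq.io`); only rows whose
    substitution matches ``spec`` contribute.  Rows without a localized
    substitution site or whose protein lacks a CDS go to the ``ambiguous``
    bucket; sites whose codon does not encode the from-residue are
    ``rejected``.  Unique peptides are keyed by protein plus modified
    sequence, collapsing charge states and runs.
    """
    profile = CodonProfile(from_residue=spec.from_residue)
    for codon in sorted(spec.codon_family):
        profile.counts[codon] = 0
        profile.intensity[codon] = 0.0

    sub = matches[
        (matches["sub_from"] == spec.from_residue)
        & (matches["sub_to"] == spec.to_residue)
    ]
    seen: set = set()
    for row in sub.itertuples(index=False):
        pos = row.sub_pos
        if pd.isna(pos):
            profile.ambiguous.append((row.protein_id, row.modified_sequence))
            continue
        record = cds_index.get(row.protein_id)
        if record is None:
            profile.ambiguous.append((row.protein_id, row.modified_sequence))
            continue
        codon = residue_codon(record, int(pos))
        if GENETIC_CODE.get(codon) != spec.from_residue:
            profile.rejected.append(
                (row.protein_id, int(pos), codon, row.modified_sequence)
            )
            continue
        key = (row.protein_id, row.modified_sequence)
        if key not in seen:
            seen.add(key)
            profile.counts[codon] += 1
        profile.intensity[codon] += float(row.intensity)
    return profile
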