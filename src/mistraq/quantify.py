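"""Headline mistranslation statistics from observed peptide reports.

Two estimators are computed per strain:

* **unique-peptide frequency** — unique substituted peptides whose
  non-mistranslated sibling was also observed, divided by all unique
  peptides containing the target amino acid, as a percentage.  The sibling
  requirement guards against false substitution calls: a genuine
  misincorporation event leaves most protein molecules wild type, so the
  unsubstituted peptide with the same coordinates should be present too.
* **intensity fraction** — summed intensity of substituted peptides over
  the summed intensity of all peptides, per replicate, as a percentage.
  This weighs each event by how much protein actually carries it and is the
  better estimate of the mistranslated share of the proteome.

Reports are pandas DataFrames with the precursor-report schema documented
in :mod:`mistraq.io`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .chem import SubstitutionSpec
from .codons import CdsRecord, residue_codon

logger = logging.getLogger(__name__)


def _unique_peptides(frame: pd.DataFrame) -> pd.DataFrame:
    """Collapse to unique peptides: one row per (protein, modified sequence).

    The unique-peptide key is the base sequence plus its full modification
    string (encoded in ``modified_sequence``), collapsed across charge
    states, runs and replicates.
    """
    return frame.drop_duplicates(subset=["protein_id", "modified_sequence"])


def _revert_substitution(row) -> str:
    seq = list(row.base_sequence)
    offset = int(row.sub_pos) - int(row.start)
    seq[offset] = row.sub_from
    return "".join(seq)


def unique_peptide_frequency(
    matches: pd.DataFrame,
    spec: SubstitutionSpec,
    codon_restricted: bool = False,
    cds_index: Optional[Mapping[str, CdsRecord]] = None,
) -> float:
    """Sibling-filtered unique-peptide mistranslation frequency (percent).

    Numerator: unique substituted peptides whose coordinate-identical
    wild-type sibling is also observed.  Denominator: unique wild-type
    peptides containing the target amino acid, plus the accepted substituted
    peptides themselves.  ``codon_restricted`` narrows the wild-type part of
    the denominator to peptides in which at least one target residue is
    encoded by one of the substitution's target codons (requires
    ``cds_index``).
    """
    wild = matches[matches["sub_pos"].isna()]
    sub = matches[
        (matches["sub_from"] == spec.from_residue)
        & (matches["sub_to"] == spec.to_residue)
    ]

    wild_unique = _unique_peptides(wild)
    sibling_keys = set(
        zip(wild_unique["protein_id"], wild_unique["start"], wild_unique["base_sequence"])
    )

    n_accepted = 0
    for row in _unique_peptides(sub).itertuples(index=False):
        if pd.isna(row.sub_pos):
            continue
        key = (row.protein_id, row.start, _revert_substitution(row))
        if key in sibling_keys:
            n_accepted += 1

    target = spec.from_residue
    contains = wild_unique["base_sequence"].str.contains(target, regex=False)
    candidates = wild_unique[contains]
    if codon_restricted:
        if cds_index is None:
            raise ValueError("codon_restricted mode requires a cds_index")
        keep = []
        for row in candidates.itertuples(index=False):
            record = cds_index.get(row.protein_id)
            if record is None:
                keep.append(False)
                continue
            ok = False
            for offset, aa in enumerate(row.base_sequence):
                if aa != target:
                    continue
                codon = residue_codon(record, int(row.start) + offset)
                if codon in spec.target_codons:
                    ok = True
                    break
            keep.append(ok)
        candidates = candidates[np.asarray(keep, dtype=bool)]
    denominator = len(candidates) + n_accepted

    if denominator == 0:
        logger.warning(
            "no peptides containing %r observed; frequency undefined", target
        )
        return float("nan")
    return 100.0 * n_accepted / denominator


@dataclass
class IntensityFraction:
    """Per-replicate intensity fractions (percent) with mean and SD."""

    per_replicate: dict
    mean: float
    sd: float


def intensity_fraction(
    matches: pd.DataFrame, spec: SubstitutionSpec
) -> IntensityFraction:
    """Mistranslated share of total peptide intensity, per replicate."""
    is_sub = (matches["sub_from"] == spec.from_residue) & (
        matches["sub_to"] == spec.to_residue
    )
    per_rep: dict = {}
    for rep, group in matches.groupby("replicate_id"):
        total = group["intensity"].sum()
        if total <= 0:
            logger.warning("replicate %s has zero total intensity", rep)
            per_rep[rep] = float("nan")
            continue
        per_rep[rep] = 100.0 * group.loc[is_sub, "intensity"].sum() / total
    values = np.array([v for v in per_rep.values() if np.isfinite(v)])
    mean = float(values.mean()) if values.size else float("nan")
    sd = float(values.std(ddof=1)) if values.size > 1 else float("nan")
    return IntensityFraction(per_rep, mean, sd)


@dataclass
class FrequencyEstimate:
    """Per-strain mistranslation estimates and a comparison to control."""

    strain_id: str
    substitution: str
    unique_pct: float
    intensity_pct: float
    per_replicate_unique: dict = field(default_factory=dict)
    per_replicate_intensity: dict = field(default_factory=dict)
    unique_mean: float = float("nan")
    unique_sd: float = float("nan")
    intensity_mean: float = float("nan")
    intensity_sd: float = float("nan")
    p_vs_control: float = float("nan")
    adj_p_vs_control: float = float("nan")


def _per_replicate_unique(
    matches: pd.DataFrame, spec: SubstitutionSpec
) -> dict:
    return {
        rep: unique_peptide_frequency(group, spec)
        for rep, group in matches.groupby("replicate_id")
    }


def frequency_report(
    matches: pd.DataFrame,
    strain_specs: Mapping[str, SubstitutionSpec],
    control_id: str,
) -> list[FrequencyEstimate]:
    """Frequency estimates for every strain plus t-tests against control.

    Each mistranslating strain is scored with its own substitution spec; the
    control strain is scored once per spec so that the comparison is
    like-with-like.  Two-sample t-tests on per-replicate intensity fractions
    are Bonferroni-adjusted over the number of strain comparisons.
    """
    control = matches[matches["strain_id"] == control_id]
    strains = [s for s in strain_specs if s != control_id]
    estimates: list[FrequencyEstimate] = []
    raw_ps: list[float] = []

    for strain in strains:
        spec = strain_specs[strain]
        frame = matches[matches["strain_id"] == strain]
        est = _estimate(strain, spec, frame)
        ctl_vals = [
            v
            for v in intensity_fraction(control, spec).per_replicate.values()
            if np.isfinite(v)
        ]
        strain_vals = [
            v for v in est.per_replicate_intensity.values() if np.isfinite(v)
        ]
        if len(ctl_vals) >= 2 and len(strain_vals) >= 2:
            if np.allclose(strain_vals, ctl_vals[: len(strain_vals)]) and (
                np.std(strain_vals) == 0 and np.std(ctl_vals) == 0
            ):
                p = 1.0
            else:
                p = float(
                    sps.ttest_ind(strain_vals, ctl_vals, equal_var=True).pvalue
                )
                if not np.isfinite(p):
                    p = 1.0
        else:
            p = float("nan")
        est.p_vs_control = p
        raw_ps.append(p)
        estimates.append(est)

    m = len(strains)
    for est in estimates:
        if np.isfinite(est.p_vs_control):
            est.adj_p_vs_control = min(1.0, m * est.p_vs_control)

    # control summarized under each spec, reported without a test
    for strain in strains:
        spec = strain_specs[strain]
        est = _estimate(f"{control_id}[{spec.name}]", spec, control)
        estimates.append(est)
    return estimates


def _estimate(
    label: str, spec: SubstitutionSpec, frame: pd.DataFrame
) -> FrequencyEstimate:
    ifrac = intensity_fraction(frame, spec)
    per_unique = _per_replicate_unique(frame, spec)
    uvals = np.array([v for v in per_unique.values() if np.isfinite(v)])
    return FrequencyEstimate(
        strain_id=label,
        substitution=spec.name,
        unique_pct=unique_peptide_frequency(frame, spec),
        intensity_pct=ifrac.mean,
        per_replicate_unique=per_unique,
        per_replicate_intensity=ifrac.per_replicate,
        unique_mean=float(uvals.mean()) if uvals.size else float("nan"),
        unique_sd=float(uvals.std(ddof=1)) if uvals.size > 1 else float("nan"),
        intensity_mean=ifrac.mean,
        intensity_sd=ifrac.sd,
    )


def frequency_table(estimates: Sequence[FrequencyEstimate]) -> pd.DataFrame:
    """Flatten estimates into a summary frame for TSV export."""
    return pd.DataFrame(
        {
            "strain_id": [e.strain_id for e in estimates],
            "substitution": [e.substitution for e in estimates],
            "unique_pct": [e.unique_pct for e in estimates],
            "intensity_pct_mean": [e.intensity_mean for e in estimates],
            "intensity_pct_sd": [e.intensity_sd for e in estimates],
            "p_vs_control": [e.p_vs_control for e in estimates],
            "adj_p_vs_control": [e.adj_p_vs_control for e in estimates],
        }
    )
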