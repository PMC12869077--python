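"""Synthetic ORFeome and identification reports with known ground truth.

The generator emulates the study design this package analyzes: a yeast-like
ORFeome with realistic codon usage, four strains (an empty-vector control
plus Pro->Ala, Pro->Ser and Arg->Ser mistranslators) in six biological
replicates, log-normal precursor intensities with replicate noise, logistic
detection in log-intensity, per-codon misincorporation, and phosphosites
including phospho on misinserted serines with a positional +1-proline bias.

Ground truth (which sites were substituted, at which codon, the planted
intensity fraction, the shifted proteins, the spiked kinase, the novel
phosphosites) is returned in a manifest so that every downstream estimator
can be checked for parameter recovery.

Mechanics of the mistranslation model: each target-residue site is selected
for detectable misincorporation by a per-codon Bernoulli draw; a selected
site diverts a fixed fraction of its host peptide's intensity into the
substituted peptide.  That fraction is calibrated once per simulation so
the substituted share of total intensity equals the strain's configured
intensity fraction exactly before noise and detection.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import io as mio
from .chem import (
    ARG_TO_SER,
    PRO_TO_ALA,
    PRO_TO_SER,
    SubstitutionSpec,
)
from .codons import GENETIC_CODE, CdsRecord, validate_cds
from .digestion import (
    LYSC,
    TRYPSIN_LYSC,
    SubstitutionSite,
    TheoreticalPeptide,
    digest,
)

# S. cerevisiae-like codon usage, relative weights per thousand codons.
# Sense codons only; marginals over synonymous families set both the
# amino-acid composition and the within-family codon choice of simulated
# ORFs.
DEFAULT_CODON_USAGE: dict[str, float] = {
    "TTT": 26.1, "TTC": 18.4, "TTA": 26.2, "TTG": 27.2,
    "CTT": 12.3, "CTC": 5.4, "CTA": 13.4, "CTG": 10.5,
    "ATT": 30.1, "ATC": 17.2, "ATA": 17.8, "ATG": 20.9,
    "GTT": 22.1, "GTC": 11.8, "GTA": 11.8, "GTG": 10.8,
    "TCT": 23.5, "TCC": 14.2, "TCA": 18.7, "TCG": 8.6,
    "AGT": 14.2, "AGC": 9.8,
    "CCT": 13.5, "CCC": 6.8, "CCA": 18.3, "CCG": 5.3,
    "ACT": 20.3, "ACC": 12.7, "ACA": 17.8, "ACG": 8.0,
    "GCT": 21.2, "GCC": 12.6, "GCA": 16.2, "GCG": 6.2,
    "TAT": 18.8, "TAC": 14.8,
    "CAT": 13.6, "CAC": 7.8,
    "CAA": 27.3, "CAG": 12.1,
    "AAT": 35.7, "AAC": 24.8,
    "AAA": 41.9, "AAG": 30.8,
    "GAT": 37.6, "GAC": 20.2,
    "GAA": 45.6, "GAG": 19.2,
    "TGT": 8.1, "TGC": 4.8, "TGG": 10.4,
    "CGT": 6.4, "CGC": 2.6, "CGA": 3.0, "CGG": 1.7,
    "AGA": 21.3, "AGG": 9.2,
    "GGT": 23.9, "GGC": 9.8, "GGA": 10.9, "GGG": 6.0,
}


@dataclass(frozen=True)
class StrainConfig:
    """One simulated strain.

    ``site_rates`` gives, per target codon, the probability that a site
    encoded by that codon carries detectable misincorporation;
    ``intensity_fraction_pct`` is the substituted share of total peptide
    intensity the strain is calibrated to (percent).
    """

    strain_id: str
    substitution: Optional[SubstitutionSpec] = None
    site_rates: Mapping[str, float] = field(default_factory=dict)
    intensity_fraction_pct: float = 0.0

    def __post_init__(self):
        for codon, rate in self.site_rates.items():
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"rate for {codon} outside [0, 1]: {rate}")
            if self.substitution is None:
                raise ValueError("site_rates given without a substitution")
            if GENETIC_CODE.get(codon) != self.substitution.from_residue:
                raise ValueError(
                    f"{codon} does not encode "
                    f"{self.substitution.from_residue!r}"
                )


def default_strains() -> Tuple[StrainConfig, ...]:
    """The four study strains at their observed mistranslation scale.

    Site-selection rates are CCA/AGA-dominant (the Watson-Crick codon of
    each mutant anticodon) and are scaled so the simulated unique-peptide
    frequencies and intensity fractions fall in the observed range
    (roughly 3-7% unique, 0.25-1% of total intensity).
    """
    return (
        StrainConfig("EV"),
        StrainConfig(
            "pro_to_ala",
            PRO_TO_ALA,
            {"CCA": 0.081, "CCT": 0.027, "CCC": 0.014, "CCG": 0.014},
            intensity_fraction_pct=0.73,
        ),
        StrainConfig(
            "pro_to_ser",
            PRO_TO_SER,
            {"CCA": 0.100, "CCT": 0.033, "CCC": 0.017, "CCG": 0.017},
            intensity_fraction_pct=0.98,
        ),
        StrainConfig(
            "arg_to_ser",
            ARG_TO_SER,
            {"AGA": 0.046},
            intensity_fraction_pct=0.25,
        ),
    )


@dataclass
class SimulationConfig:
    """All knobs of the generator; the defaults are the study conditions
    scaled down to a desk-size ORFeome (300 genes, 4 strains x 6
    replicates)."""

    n_genes: int = 300
    length_log_mean: float = math.log(350.0)
    length_log_sd: float = 0.45
    min_length: int = 60
    max_length: int = 1200
    codon_usage: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CODON_USAGE)
    )
    strains: Tuple[StrainConfig, ...] = field(default_factory=default_strains)
    n_replicates: int = 6
    # log-normal gene abundance (natural-log parameters) and per-peptide
    # response factor
    intensity_log_mean: float = math.log(1e6)
    intensity_log_sd: float = 1.2
    peptide_factor_sd: float = 0.5
    # multiplicative replicate noise; 0.13 on the natural log corresponds
    # to a ~13% CV, matching a precise label-free experiment
    replicate_noise_sd: float = 0.13
    phospho_extra_noise_sd: float = 0.12
    # logistic detection in log10 intensity
    detection_midpoint_log10: float = 2.0
    detection_scale: float = 0.35
    # fraction of rows emitted with a failing q-value, to exercise filters
    decoy_q_fraction: float = 0.02
    # phosphoproteome model
    canonical_phospho_prob: float = 0.05
    canonical_stoich_log_mean: float = math.log(0.05)
    canonical_stoich_log_sd: float = 0.8
    # a misinserted serine is phosphorylated with novel_phospho_prob,
    # multiplied by motif_bias_weight when followed by proline (a
    # proline-directed-kinase preference), capped at 0.95
    novel_phospho_prob: float = 0.1
    novel_stoich_log_mean: float = math.log(0.02)
    novel_stoich_log_sd: float = 0.6
    motif_bias_weight: float = 9.0
    localization_beta_a: float = 12.0
    localization_beta_b: float = 1.5
    # planted differential signal
    n_shifted_proteins: int = 30
    protein_shift_log2: float = 1.0
    # kinase-substrate model
    n_kinases: int = 12
    substrates_per_kinase: int = 15
    planted_kinase: Optional[str] = "KIN01"
    planted_kinase_strain: str = "pro_to_ser"
    planted_kinase_shift_log2: float = -1.2
    # proteome report
    max_peptides_per_protein: int = 5
    seed: int = 1

    def __post_init__(self):
        if self.length_log_sd <= 0:
            raise ValueError("degenerate protein length distribution")
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")

    def strain(self, strain_id: str) -> StrainConfig:
        for s in self.strains:
            if s.strain_id == strain_id:
                return s
        raise KeyError(strain_id)


def _rng(seed: int, stage: int) -> np.random.Generator:
    # independent, reproducible substream per pipeline stage
    return np.random.default_rng(np.random.SeedSequence([int(seed), stage]))


def generate_orfeome(
    config: SimulationConfig, seed: Optional[int] = None
) -> list[CdsRecord]:
    """Sample an ORFeome: ATG start, sense codons per usage weights, one
    terminal stop.  Translation consistency holds by construction and is
    verified before returning."""
    rng = _rng(config.seed if seed is None else seed, 0)
    codons = sorted(config.codon_usage)
    weights = np.array([config.codon_usage[c] for c in codons], dtype=float)
    probs = weights / weights.sum()
    records = []
    width = max(4, len(str(config.n_genes)))
    for g in range(config.n_genes):
        length = int(
            np.clip(
                round(rng.lognormal(config.length_log_mean, config.length_log_sd)),
                config.min_length,
                config.max_length,
            )
        )
        body = rng.choice(codons, size=length - 1, p=probs)
        cds = "ATG" + "".join(body) + "TAA"
        protein = "M" + "".join(GENETIC_CODE[c] for c in body)
        records.append(
            validate_cds(CdsRecord(f"G{g:0{width}d}", cds, protein))
        )
    return records


def _detection_prob(
    intensity: np.ndarray, config: SimulationConfig
) -> np.ndarray:
    z = (np.log10(np.maximum(intensity, 1e-12)) - config.detection_midpoint_log10)
    return 1.0 / (1.0 + np.exp(-z / config.detection_scale))


def _draw_q(rng, n: int, config: SimulationConfig) -> np.ndarray:
    q = rng.uniform(0.0, 0.009, size=n)
    decoy = rng.random(n) < config.decoy_q_fraction
    q[decoy] = rng.uniform(0.011, 0.2, size=int(decoy.sum()))
    return q


@dataclass
class SimulationResult:
    orfeome: list
    proteome: dict
    manifest: dict
    mistranslation_report: Optional[pd.DataFrame] = None
    proteome_report: Optional[pd.DataFrame] = None
    phospho_report: Optional[pd.DataFrame] = None
    kinase_substrates: Optional[pd.DataFrame] = None
    rsa: Optional[pd.DataFrame] = None


def _select_sites(
    record: CdsRecord, strain: StrainConfig, rng
) -> list[Tuple[int, str]]:
    """Bernoulli site selection: (1-based position, codon) pairs."""
    if strain.substitution is None or not strain.site_rates:
        return []
    spec = strain.substitution
    out = []
    for i, aa in enumerate(record.protein):
        if aa != spec.from_residue:
            continue
        codon = record.cds[3 * i : 3 * i + 3]
        rate = strain.site_rates.get(codon, 0.0)
        if rate > 0 and rng.random() < rate:
            out.append((i + 1, codon))
    return out


def _substituted_peptide(
    record: CdsRecord,
    position: int,
    spec: SubstitutionSpec,
    rule,
    length_range,
) -> Optional[TheoreticalPeptide]:
    """The digest product of the mutated protein that covers the site."""
    mutated = (
        record.protein[: position - 1]
        + spec.to_residue
        + record.protein[position:]
    )
    site = SubstitutionSite(position, spec.from_residue, spec.to_residue)
    for pep in digest(mutated, rule, 0, length_range, record.gene_id):
        if pep.covers(position):
            return TheoreticalPeptide(
                sequence=pep.sequence,
                protein_id=record.gene_id,
                start=pep.start,
                end=pep.end,
                missed_cleavages=0,
                substitution_sites=(site,),
            )
    return None


def simulate_reports(
    orfeome: Sequence[CdsRecord],
    config: SimulationConfig,
    seed: Optional[int] = None,
    include: Sequence[str] = ("mistranslation", "proteome", "phospho"),
) -> SimulationResult:
    """Generate per-strain, per-replicate identification reports.

    The mistranslation report uses a LysC digest; the whole-proteome and
    phospho reports use trypsin+LysC, mirroring how such samples are
    prepared.  ``include`` limits which reports are built (the others stay
    None), which keeps repeated parameter-recovery runs cheap.
    """
    seed = config.seed if seed is None else seed
    proteome = {r.gene_id: r.protein for r in orfeome}
    cds_index = {r.gene_id: r for r in orfeome}

    abun_rng = _rng(seed, 1)
    abundance = {
        r.gene_id: abun_rng.lognormal(
            config.intensity_log_mean, config.intensity_log_sd
        )
        for r in orfeome
    }

    # site selection is the strain's biology: shared between the
    # mistranslation and phospho reports
    selected: dict[str, dict[str, list]] = {}
    for strain in config.strains:
        srng = _rng(seed, 10 + _strain_index(config, strain.strain_id))
        selected[strain.strain_id] = {
            r.gene_id: _select_sites(r, strain, srng) for r in orfeome
        }

    manifest: dict = {
        "seed": int(seed),
        "n_genes": config.n_genes,
        "n_replicates": config.n_replicates,
        "strains": {},
    }
    for strain in config.strains:
        per_codon: dict[str, int] = {}
        if strain.substitution is not None:
            for codon in sorted(strain.substitution.codon_family):
                per_codon[codon] = 0
            for sites in selected[strain.strain_id].values():
                for _pos, codon in sites:
                    per_codon[codon] += 1
        total = sum(per_codon.values())
        manifest["strains"][strain.strain_id] = {
            "substitution": strain.substitution.name
            if strain.substitution
            else None,
            "site_rates": dict(strain.site_rates),
            "intensity_fraction_pct": strain.intensity_fraction_pct,
            "selected_site_counts": per_codon,
            "expected_codon_profile": {
                c: n / total for c, n in per_codon.items()
            }
            if total
            else {},
        }

    result = SimulationResult(
        orfeome=list(orfeome), proteome=proteome, manifest=manifest
    )

    if "mistranslation" in include:
        result.mistranslation_report = _mistranslation_report(
            orfeome, config, seed, abundance, selected, manifest
        )
    if "proteome" in include:
        result.proteome_report = _proteome_report(
            orfeome, config, seed, abundance, manifest
        )
    if "phospho" in include:
        (
            result.phospho_report,
            result.kinase_substrates,
            result.rsa,
        ) = _phospho_report(orfeome, config, seed, abundance, selected, manifest)
    return result


def _strain_index(config: SimulationConfig, strain_id: str) -> int:
    for i, s in enumerate(config.strains):
        if s.strain_id == strain_id:
            return i
    raise KeyError(strain_id)


def _replicate_rows(
    species: pd.DataFrame,
    config: SimulationConfig,
    rng,
    strain_id: str,
    extra_noise_sd: float = 0.0,
) -> pd.DataFrame:
    """Expand a species table into per-replicate detected rows."""
    frames = []
    n = len(species)
    for rep in range(1, config.n_replicates + 1):
        noise = rng.lognormal(0.0, config.replicate_noise_sd, size=n)
        if extra_noise_sd > 0:
            noise = noise * rng.lognormal(0.0, extra_noise_sd, size=n)
        intensity = species["intensity"].to_numpy() * noise
        detected = rng.random(n) < _detection_prob(intensity, config)
        rows = species.loc[detected].copy()
        rows["intensity"] = intensity[detected]
        rows["replicate_id"] = f"rep{rep}"
        rows["run_id"] = f"{strain_id}_rep{rep}"
        rows["global_q"] = _draw_q(rng, len(rows), config)
        frames.append(rows)
    out = pd.concat(frames, ignore_index=True)
    out["strain_id"] = strain_id
    return out


def _mistranslation_report(
    orfeome, config, seed, abundance, selected, manifest
) -> pd.DataFrame:
    pep_rng = _rng(seed, 2)
    length_range = (7, 50)

    # wild-type LysC peptide space with a per-peptide response factor
    wild_peptides: list[dict] = []
    host_of: dict[tuple, int] = {}  # (gene, protein position) -> index
    for record in orfeome:
        for pep in digest(record.protein, LYSC, 0, length_range, record.gene_id):
            base = abundance[record.gene_id] * pep_rng.lognormal(
                0.0, config.peptide_factor_sd
            )
            idx = len(wild_peptides)
            wild_peptides.append(
                {
                    "protein_id": record.gene_id,
                    "base_sequence": pep.sequence,
                    "start": pep.start,
                    "end": pep.end,
                    "base_intensity": base,
                }
            )
            for pos in range(pep.start, pep.end + 1):
                host_of[(record.gene_id, pos)] = idx

    frames = []
    for strain in config.strains:
        srng = _rng(seed, 100 + _strain_index(config, strain.strain_id))
        spec = strain.substitution
        wild_int = np.array([w["base_intensity"] for w in wild_peptides])
        sub_rows: list[dict] = []
        n_planted = 0

        if spec is not None:
            hosts, positions = [], []
            for record in orfeome:
                for pos, _codon in selected[strain.strain_id][record.gene_id]:
                    idx = host_of.get((record.gene_id, pos))
                    if idx is None:  # site only in length-filtered peptides
                        continue
                    hosts.append(idx)
                    positions.append((record.gene_id, pos))
            s_sel = sum(wild_int[i] for i in hosts)
            s_tot = wild_int.sum()
            r_conv = (
                (strain.intensity_fraction_pct / 100.0) * s_tot / s_sel
                if s_sel > 0
                else 0.0
            )
            manifest["strains"][strain.strain_id]["conversion_fraction"] = r_conv
            cds_index = {r.gene_id: r for r in orfeome}
            for idx, (gene, pos) in zip(hosts, positions):
                pep = _substituted_peptide(
                    cds_index[gene], pos, spec, LYSC, length_range
                )
                if pep is None:
                    continue
                diverted = r_conv * wild_peptides[idx]["base_intensity"]
                wild_int[idx] = max(wild_int[idx] - diverted, 0.0)
                sub_rows.append(
                    {
                        "protein_id": gene,
                        "base_sequence": pep.sequence,
                        "modified_sequence": mio.build_modified_sequence(
                            pep.sequence, pep.substitution_sites
                        ),
                        "start": pep.start,
                        "intensity": diverted,
                        "sub_pos": pos,
                    }
                )
                n_planted += 1
            manifest["strains"][strain.strain_id][
                "n_planted_substituted_peptides"
            ] = n_planted

        species = pd.DataFrame(
            {
                "protein_id": [w["protein_id"] for w in wild_peptides],
                "base_sequence": [w["base_sequence"] for w in wild_peptides],
                "modified_sequence": [
                    w["base_sequence"] for w in wild_peptides
                ],
                "start": [w["start"] for w in wild_peptides],
                "intensity": wild_int,
                "sub_pos": np.nan,
            }
        )
        if sub_rows:
            species = pd.concat(
                [species, pd.DataFrame(sub_rows)], ignore_index=True
            )
        species["charge"] = srng.choice([2, 3], size=len(species), p=[0.7, 0.3])
        rows = _replicate_rows(species, config, srng, strain.strain_id)
        frames.append(rows)

    report = pd.concat(frames, ignore_index=True)
    if report["sub_pos"].notna().any():
        sub_mask = report["sub_pos"].notna()
        spec_of = {
            s.strain_id: s.substitution
            for s in config.strains
            if s.substitution is not None
        }
        report["sub_from"] = pd.NA
        report["sub_to"] = pd.NA
        for strain_id, spec in spec_of.items():
            m = sub_mask & (report["strain_id"] == strain_id)
            report.loc[m, "sub_from"] = spec.from_residue
            report.loc[m, "sub_to"] = spec.to_residue
    else:
        report["sub_from"] = pd.NA
        report["sub_to"] = pd.NA

    # detection drops of planted species are part of the ground truth
    for strain in config.strains:
        if strain.substitution is None:
            continue
        planted = manifest["strains"][strain.strain_id].get(
            "n_planted_substituted_peptides", 0
        )
        observed = report[
            (report["strain_id"] == strain.strain_id)
            & report["sub_pos"].notna()
        ]["modified_sequence"].nunique()
        manifest["strains"][strain.strain_id]["n_substituted_detected"] = int(
            observed
        )
        manifest["strains"][strain.strain_id]["n_substituted_dropped"] = int(
            planted - observed
        )
    return report[
        [
            "run_id",
            "strain_id",
            "replicate_id",
            "protein_id",
            "base_sequence",
            "modified_sequence",
            "start",
            "charge",
            "intensity",
            "global_q",
            "sub_pos",
            "sub_from",
            "sub_to",
        ]
    ]


def _proteome_report(orfeome, config, seed, abundance, manifest) -> pd.DataFrame:
    rng = _rng(seed, 3)
    length_range = (7, 50)

    genes = [r.gene_id for r in orfeome]
    shifted_idx = rng.choice(
        len(genes), size=min(config.n_shifted_proteins, len(genes)), replace=False
    )
    shifts = {
        genes[g]: config.protein_shift_log2 * (1 if k % 2 == 0 else -1)
        for k, g in enumerate(sorted(shifted_idx))
    }
    manifest["shifted_proteins"] = {g: float(s) for g, s in shifts.items()}

    species_rows = []
    for record in orfeome:
        peps = digest(record.protein, TRYPSIN_LYSC, 0, length_range, record.gene_id)
        for pep in peps[: config.max_peptides_per_protein]:
            species_rows.append(
                {
                    "protein_id": record.gene_id,
                    "peptide": pep.sequence,
                    "base_intensity": abundance[record.gene_id]
                    * rng.lognormal(0.0, config.peptide_factor_sd),
                }
            )
    species = pd.DataFrame(species_rows)

    frames = []
    for strain in config.strains:
        srng = _rng(seed, 200 + _strain_index(config, strain.strain_id))
        factor = np.ones(len(species))
        if strain.substitution is not None:
            shifted = species["protein_id"].map(shifts).fillna(0.0).to_numpy()
            factor = np.exp2(shifted)
        tbl = species.assign(intensity=species["base_intensity"] * factor)[
            ["protein_id", "peptide", "intensity"]
        ]
        rows = _replicate_rows(tbl, config, srng, strain.strain_id)
        rows["sample_id"] = rows["strain_id"] + "." + rows["replicate_id"]
        frames.append(rows)
    report = pd.concat(frames, ignore_index=True)
    return report[
        [
            "run_id",
            "sample_id",
            "strain_id",
            "replicate_id",
            "protein_id",
            "peptide",
            "intensity",
            "global_q",
        ]
    ]


def _phospho_report(
    orfeome, config, seed, abundance, selected, manifest
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    rng = _rng(seed, 4)
    length_range = (7, 50)
    cds_index = {r.gene_id: r for r in orfeome}

    shifts = manifest.get("shifted_proteins", {})

    # canonical phosphosites on encoded S/T/Y
    canonical: list[dict] = []
    for record in orfeome:
        for i, aa in enumerate(record.protein):
            if aa in "STY" and rng.random() < config.canonical_phospho_prob:
                canonical.append(
                    {
                        "protein_id": record.gene_id,
                        "position": i + 1,
                        "residue": aa,
                        "stoich": rng.lognormal(
                            config.canonical_stoich_log_mean,
                            config.canonical_stoich_log_sd,
                        ),
                        # localizability is a property of the site (its
                        # flanking fragment-ion context), not of one scan
                        "conf_base": rng.beta(
                            config.localization_beta_a,
                            config.localization_beta_b,
                        ),
                    }
                )
    canonical_df = pd.DataFrame(canonical)

    # kinase-substrate annotation over canonical sites
    k_rng = _rng(seed, 5)
    n_annot = min(
        len(canonical_df), config.n_kinases * config.substrates_per_kinase
    )
    annot_rows = []
    if n_annot:
        chosen = k_rng.choice(len(canonical_df), size=n_annot, replace=False)
        for j, idx in enumerate(chosen):
            row = canonical_df.iloc[idx]
            kinase = f"KIN{j % config.n_kinases + 1:02d}"
            annot_rows.append(
                {
                    "kinase": kinase,
                    "protein": row["protein_id"],
                    "site": int(row["position"]),
                }
            )
    annotations = pd.DataFrame(annot_rows)
    planted_substrates: set = set()
    if config.planted_kinase is not None and len(annotations):
        planted_substrates = {
            f"{r.protein}:{r.site}"
            for r in annotations[
                annotations["kinase"] == config.planted_kinase
            ].itertuples(index=False)
        }
    manifest["planted_kinase"] = config.planted_kinase
    manifest["planted_kinase_strain"] = (
        config.planted_kinase_strain if config.planted_kinase else None
    )
    manifest["planted_kinase_shift_log2"] = (
        config.planted_kinase_shift_log2 if config.planted_kinase else None
    )

    # novel sites: phospho on misinserted serines, +1-proline biased
    novel: dict[str, list[dict]] = {}
    n_rng = _rng(seed, 6)
    for strain in config.strains:
        spec = strain.substitution
        if spec is None or spec.to_residue != "S":
            continue
        candidates = []
        for record in orfeome:
            for pos, _codon in selected[strain.strain_id][record.gene_id]:
                nxt = (
                    record.protein[pos]
                    if pos < len(record.protein)
                    else None
                )
                candidates.append((record.gene_id, pos, nxt == "P"))
        p_plus = min(0.95, config.novel_phospho_prob * config.motif_bias_weight)
        p_minus = config.novel_phospho_prob
        picked = [
            c
            for c in candidates
            if n_rng.random() < (p_plus if c[2] else p_minus)
        ]
        novel[strain.strain_id] = [
            {
                "protein_id": gene,
                "position": pos,
                "plus1_proline": bool(is_p),
                "stoich": n_rng.lognormal(
                    config.novel_stoich_log_mean, config.novel_stoich_log_sd
                ),
                "conf_base": n_rng.beta(
                    config.localization_beta_a, config.localization_beta_b
                ),
            }
            for gene, pos, is_p in picked
        ]
        manifest["strains"][strain.strain_id]["novel_phosphosites"] = [
            [d["protein_id"], d["position"], d["plus1_proline"]]
            for d in novel[strain.strain_id]
        ]

    def _site_peptide(gene: str, pos: int, spec=None):
        protein = proteome_seq = cds_index[gene].protein
        if spec is not None:
            proteome_seq = (
                protein[: pos - 1] + spec.to_residue + protein[pos:]
            )
        for pep in digest(proteome_seq, TRYPSIN_LYSC, 0, length_range, gene):
            if pep.covers(pos):
                return pep
        return None

    frames = []
    for strain in config.strains:
        srng = _rng(seed, 300 + _strain_index(config, strain.strain_id))
        rows = []
        is_control = strain.substitution is None
        for site in canonical_df.itertuples(index=False):
            pep = _site_peptide(site.protein_id, int(site.position))
            if pep is None:
                continue
            site_id = f"{site.protein_id}:{int(site.position)}"
            log2_shift = 0.0
            if not is_control:
                log2_shift += shifts.get(site.protein_id, 0.0)
                if (
                    site_id in planted_substrates
                    and strain.strain_id == config.planted_kinase_strain
                ):
                    log2_shift += config.planted_kinase_shift_log2
            intensity = (
                abundance[site.protein_id] * site.stoich * 2.0**log2_shift
            )
            rows.append(
                {
                    "protein_id": site.protein_id,
                    "base_sequence": pep.sequence,
                    "modified_sequence": mio.build_modified_sequence(
                        pep.sequence,
                        modifications=[(int(site.position), "Phospho")],
                    ),
                    "start": pep.start,
                    "intensity": intensity,
                    "phospho_pos": int(site.position),
                    "sub_pos": np.nan,
                    "sub_from": pd.NA,
                    "sub_to": pd.NA,
                    "conf_base": site.conf_base,
                }
            )
        for entry in novel.get(strain.strain_id, []):
            spec = strain.substitution
            pep = _site_peptide(entry["protein_id"], entry["position"], spec)
            if pep is None:
                continue
            sub_site = SubstitutionSite(
                entry["position"], spec.from_residue, spec.to_residue
            )
            base = pep.sequence
            intensity = abundance[entry["protein_id"]] * entry["stoich"]
            rows.append(
                {
                    "protein_id": entry["protein_id"],
                    "base_sequence": base,
                    "modified_sequence": mio.build_modified_sequence(
                        base,
                        substitutions=[sub_site],
                        modifications=[(entry["position"], "Phospho")],
                    ),
                    "start": pep.start,
                    "intensity": intensity,
                    "phospho_pos": entry["position"],
                    "sub_pos": entry["position"],
                    "sub_from": spec.from_residue,
                    "sub_to": spec.to_residue,
                    "conf_base": entry["conf_base"],
                }
            )
        species = pd.DataFrame(rows)
        species["charge"] = srng.choice([2, 3], size=len(species), p=[0.6, 0.4])
        rep_rows = _replicate_rows(
            species,
            config,
            srng,
            strain.strain_id,
            extra_noise_sd=config.phospho_extra_noise_sd,
        )
        rep_rows["peptidoform_q"] = _draw_q(srng, len(rep_rows), config)
        rep_rows["site_confidence"] = np.clip(
            rep_rows["conf_base"].to_numpy()
            + srng.normal(0.0, 0.02, size=len(rep_rows)),
            0.0,
            1.0,
        )
        rep_rows = rep_rows.drop(columns=["conf_base"])
        frames.append(rep_rows)
    report = pd.concat(frames, ignore_index=True)

    # synthetic per-residue relative solvent accessibility for every
    # phosphosite position (no planted exposure difference)
    r_rng = _rng(seed, 7)
    site_positions = report[["protein_id", "phospho_pos"]].drop_duplicates()
    rsa = site_positions.rename(columns={"phospho_pos": "position"}).copy()
    rsa["rsa"] = r_rng.beta(2.0, 2.0, size=len(rsa))

    cols = [
        "run_id",
        "strain_id",
        "replicate_id",
        "protein_id",
        "base_sequence",
        "modified_sequence",
        "start",
        "charge",
        "intensity",
        "global_q",
        "peptidoform_q",
        "site_confidence",
        "phospho_pos",
        "sub_pos",
        "sub_from",
        "sub_to",
    ]
    return report[cols], annotations, rsa


def write_outputs(result: SimulationResult, out_dir) -> None:
    """Write FASTAs, reports, annotations and the manifest to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mio.write_fasta(
        {r.gene_id: r.cds for r in result.orfeome}, out / "cds.fasta"
    )
    mio.write_fasta(result.proteome, out / "proteins.fasta")
    if result.mistranslation_report is not None:
        mio.write_report(
            result.mistranslation_report, out / "mistranslation_report.tsv"
        )
    if result.proteome_report is not None:
        mio.write_report(result.proteome_report, out / "proteome_report.tsv")
    if result.phospho_report is not None:
        mio.write_report(result.phospho_report, out / "phospho_report.tsv")
    if result.kinase_substrates is not None:
        mio.write_report(
            result.kinase_substrates, out / "kinase_substrates.tsv"
        )
    if result.rsa is not None:
        mio.write_report(result.rsa, out / "rsa.tsv")
    with open(out / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# recovery: run the full pipeline on simulated reports and compare against
# the manifest

def proteome_matrix(report: pd.DataFrame, log2: bool = True) -> pd.DataFrame:
    """Protein x sample abundance matrix via median-polish summarization."""
    from .stats import summarize_protein

    frame = report.copy()
    frame["sample_id"] = frame["strain_id"] + "." + frame["replicate_id"]
    value = np.log2(frame["intensity"]) if log2 else frame["intensity"]
    frame = frame.assign(value=value)
    samples = sorted(frame["sample_id"].unique())
    rows = {}
    for protein, group in frame.groupby("protein_id"):
        pivot = group.pivot_table(
            index="peptide", columns="sample_id", values="value", aggfunc="mean"
        ).reindex(columns=samples)
        rows[protein] = summarize_protein(pivot)
    return pd.DataFrame(rows).T.reindex(columns=samples)


def phospho_site_matrix(report: pd.DataFrame) -> pd.DataFrame:
    """Phosphosite x sample log2 intensity matrix (canonical sites only by
    default when misinserted rows are excluded upstream)."""
    frame = report.copy()
    frame["sample_id"] = frame["strain_id"] + "." + frame["replicate_id"]
    frame["site_id"] = (
        frame["protein_id"] + ":" + frame["phospho_pos"].astype(int).astype(str)
    )
    pivot = frame.pivot_table(
        index="site_id",
        columns="sample_id",
        values="intensity",
        aggfunc="sum",
    )
    return np.log2(pivot)


def _samples_of(matrix: pd.DataFrame, strain_id: str) -> list:
    return [c for c in matrix.columns if c.startswith(strain_id + ".")]


def recovery_suite(
    result: SimulationResult,
    config: SimulationConfig,
    control_id: str = "EV",
) -> dict:
    """Run the analysis pipeline on simulated reports and score it against
    the ground-truth manifest.

    Returns a nested dict with, per mistranslating strain, the recovered
    intensity fraction and codon-profile L1 error; plus differential
    true-positive recovery of planted protein shifts, the planted kinase's
    KSEA standing, and the minimum-p motif cell for novel phosphosites.
    """
    from . import phospho as ph
    from . import quantify as qt
    from . import stats as st
    from .codons import codon_profile

    report: dict = {"strains": {}}
    manifest = result.manifest
    cds_index = {r.gene_id: r for r in result.orfeome}

    if result.mistranslation_report is not None:
        mr = result.mistranslation_report
        mr = mr[mr["global_q"] <= 0.01]
        for strain in config.strains:
            if strain.substitution is None:
                continue
            spec = strain.substitution
            frame = mr[mr["strain_id"] == strain.strain_id]
            ifrac = qt.intensity_fraction(frame, spec)
            profile = codon_profile(frame, cds_index, spec)
            expected = manifest["strains"][strain.strain_id][
                "expected_codon_profile"
            ]
            freq = profile.count_frequency() or {}
            l1 = sum(
                abs(freq.get(c, 0.0) - expected.get(c, 0.0))
                for c in set(freq) | set(expected)
            )
            off_target = sum(
                v
                for c, v in freq.items()
                if expected.get(c, 0.0) == 0.0
            )
            report["strains"][strain.strain_id] = {
                "true_intensity_fraction_pct": strain.intensity_fraction_pct,
                "estimated_intensity_fraction_pct": ifrac.mean,
                "intensity_fraction_sd": ifrac.sd,
                "unique_peptide_frequency_pct": qt.unique_peptide_frequency(
                    frame, spec
                ),
                "codon_profile_l1": l1,
                "codon_profile_off_target_mass": off_target,
                "codon_profile": freq,
            }

    protein_results: dict = {}
    if result.proteome_report is not None:
        matrix = proteome_matrix(result.proteome_report)
        shifted = manifest.get("shifted_proteins", {})
        control = _samples_of(matrix, control_id)
        diff_summary = {}
        for strain in config.strains:
            if strain.substitution is None:
                continue
            res = st.differential(
                matrix, control, _samples_of(matrix, strain.strain_id)
            )
            protein_results[strain.strain_id] = res
            called = set(res.index[res["significant"]])
            truth = set(shifted)
            tp = len(called & truth)
            diff_summary[strain.strain_id] = {
                "n_called": len(called),
                "n_true_shifted": len(truth),
                "true_positive_rate": tp / len(truth) if truth else float("nan"),
                "false_discoveries": len(called - truth),
                "empirical_fdr": (len(called - truth) / len(called))
                if called
                else 0.0,
            }
        report["differential"] = diff_summary

    if result.phospho_report is not None:
        pr = result.phospho_report
        accepted = pr[
            (pr["global_q"] <= 0.01)
            & (pr["peptidoform_q"] <= 0.01)
            & (pr["site_confidence"] > 0.75)
        ]
        canonical = accepted[accepted["sub_pos"].isna()]
        site_matrix = phospho_site_matrix(canonical)
        site_protein = {
            s: s.split(":", 1)[0] for s in site_matrix.index
        }
        control = _samples_of(site_matrix, control_id)

        ksea_summary = {}
        for strain in config.strains:
            if strain.substitution is None:
                continue
            sres = st.differential(
                site_matrix, control, _samples_of(site_matrix, strain.strain_id)
            )
            prot = protein_results.get(strain.strain_id)
            if prot is not None:
                sres = st.adjust_phosphosite(sres, prot, site_protein)
            if result.kinase_substrates is not None and len(
                result.kinase_substrates
            ):
                kres = st.ksea(sres, result.kinase_substrates)
                entry = {
                    "n_reported_kinases": int(kres["reported"].sum()),
                }
                planted = manifest.get("planted_kinase")
                if (
                    planted is not None
                    and strain.strain_id == manifest.get("planted_kinase_strain")
                ):
                    direction = (
                        "down"
                        if manifest["planted_kinase_shift_log2"] < 0
                        else "up"
                    )
                    sub = kres[kres["direction"] == direction].sort_values("p")
                    ranks = {
                        k: i + 1
                        for i, k in enumerate(sub["kinase_id"].tolist())
                    }
                    entry["planted_kinase"] = planted
                    entry["planted_kinase_rank"] = ranks.get(planted)
                    prow = sub[sub["kinase_id"] == planted]
                    entry["planted_kinase_reported"] = bool(
                        prow["reported"].any()
                    )
                ksea_summary[strain.strain_id] = entry
        report["ksea"] = ksea_summary

        # novel misinserted-serine phosphosites and their motif signal
        observations = ph.collect_site_observations(accepted)
        novel_summary = {}
        for strain in config.strains:
            spec = strain.substitution
            if spec is None or spec.to_residue != "S":
                continue
            strain_obs = [
                o for o in observations if o.strain_id == strain.strain_id
            ]
            retained = ph.detect_novel_sites(
                strain_obs, n_replicates_required=config.n_replicates
            )
            background = [
                (o.protein_id, o.protein_position)
                for o in strain_obs
                if o.origin == "canonical"
            ]
            foreground = [
                (o.protein_id, o.protein_position) for o in retained
            ]
            entry = {
                "n_planted": len(
                    manifest["strains"][strain.strain_id].get(
                        "novel_phosphosites", []
                    )
                ),
                "n_retained": len(retained),
            }
            if foreground:
                motif = ph.motif_enrichment(
                    foreground, result.proteome, background
                )
                positive = motif[motif["p"] > 0]
                if len(positive):
                    best = positive.loc[positive["p"].idxmin()]
                    entry["min_p_offset"] = int(best["offset"])
                    entry["min_p_residue"] = str(best["residue"])
                    entry["min_p"] = float(best["p"])
                plus1 = motif[
                    (motif["offset"] == 1) & (motif["residue"] == "P")
                ]
                if len(plus1):
                    entry["plus1_proline_p"] = float(plus1["p"].iloc[0])
                    entry["plus1_proline_count"] = int(
                        plus1["foreground_count"].iloc[0]
                    )
                    entry["plus1_proline_n"] = int(
                        plus1["foreground_n"].iloc[0]
                    )
            novel_summary[strain.strain_id] = entry
        report["novel_phosphosites"] = novel_summary

    return report
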