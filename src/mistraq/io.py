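"""Readers and writers: FASTA, precursor/phospho report TSVs, annotations.

Report schema (tab-separated, UTF-8, '.' decimal separator)
-----------------------------------------------------------

Precursor report (one row per precursor per run):

========================  =====================================================
column                    meaning
========================  =====================================================
run_id                    acquisition run identifier
strain_id                 biological strain
replicate_id              biological replicate within strain
protein_id                protein accession (must match the FASTA)
base_sequence             plain residue sequence as observed
modified_sequence         base sequence plus annotations, ``|``-separated:
                          substitutions as ``P12S`` (from-residue, 1-based
                          protein position, to-residue) and modifications as
                          ``14(Phospho)`` (1-based protein position, name)
start                     1-based protein position of the peptide N-terminus
charge                    precursor charge state
intensity                 quantified intensity (arbitrary units, >= 0)
global_q                  run-level global q-value in [0, 1]
========================  =====================================================

The phospho report adds ``peptidoform_q``, ``site_confidence`` (PTM
localization confidence in [0, 1]) and ``phospho_pos`` (1-based protein
position of the phosphosite).  Readers derive the convenience columns
``sub_pos``/``sub_from``/``sub_to`` from ``modified_sequence``.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Tuple

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .chem import STANDARD_RESIDUES
from .digestion import SubstitutionSite

logger = logging.getLogger(__name__)

PRECURSOR_COLUMNS = [
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
]
PHOSPHO_COLUMNS = PRECURSOR_COLUMNS + [
    "peptidoform_q",
    "site_confidence",
    "phospho_pos",
]

_SUB_TOKEN = re.compile(r"^([A-Z])(\d+)([A-Z])$")
_MOD_TOKEN = re.compile(r"^(\d+)\(([^)]+)\)$")


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path) -> dict[str, str]:
    """Read a protein or DNA FASTA into an ordered id -> sequence mapping.

    Duplicate ids are rejected; lowercase sequences are uppercased with a
    warning.  Sequences must be non-empty.
    """
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate FASTA id: {rec.id}")
        seq = str(rec.seq)
        if not seq:
            raise ValueError(f"empty sequence for {rec.id}")
        if seq != seq.upper():
            logger.warning("uppercasing lowercase sequence for %s", rec.id)
            seq = seq.upper()
        records[rec.id] = seq
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def validate_protein_fasta(records: Mapping[str, str]) -> None:
    for name, seq in records.items():
        bad = set(seq) - STANDARD_RESIDUES
        if bad:
            raise ValueError(f"{name}: non-residue characters {sorted(bad)}")


def write_fasta(records: Mapping[str, str], path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()),
        str(path),
        "fasta",
    )


# ---------------------------------------------------------------------------
# modified-sequence annotation string

def build_modified_sequence(
    base_sequence: str,
    substitutions: Sequence[SubstitutionSite] = (),
    modifications: Sequence[Tuple[int, str]] = (),
) -> str:
    """Assemble the annotated sequence string (see module docstring)."""
    tokens = [base_sequence]
    for site in substitutions:
        tokens.append(f"{site.from_residue}{site.position}{site.to_residue}")
    for pos, name in modifications:
        tokens.append(f"{pos}({name})")
    return "|".join(tokens)


def parse_modified_sequence(
    text: str,
) -> tuple[str, list[SubstitutionSite], list[Tuple[int, str]]]:
    """Split an annotated sequence into base sequence, substitutions, mods."""
    tokens = text.split("|")
    base = tokens[0]
    subs: list[SubstitutionSite] = []
    mods: list[Tuple[int, str]] = []
    for token in tokens[1:]:
        m = _SUB_TOKEN.match(token)
        if m:
            subs.append(
                SubstitutionSite(int(m.group(2)), m.group(1), m.group(3))
            )
            continue
        m = _MOD_TOKEN.match(token)
        if m:
            mods.append((int(m.group(1)), m.group(2)))
            continue
        raise ValueError(f"unparseable annotation token {token!r} in {text!r}")
    return base, subs, mods


# ---------------------------------------------------------------------------
# reports

def write_report(frame: pd.DataFrame, path) -> None:
    """Write a report TSV atomically (write then rename)."""
    path = Path(path)
    tmp = path.with_suffix(path.suffix + ".tmp")
    frame.to_csv(tmp, sep="\t", index=False)
    tmp.replace(path)


def read_precursor_report(
    path,
    proteome: Optional[Mapping[str, str]] = None,
    max_q: float = 0.01,
    schema: str = "precursor",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read and validate a report TSV.

    Returns ``(accepted, rejects)``; rejects carry a ``reject_reason``
    column (``q_filter``, ``parse_error``, ``inconsistent_substitution``,
    ``bad_value``).  Accepted + rejected row counts always equal the input
    row count.  When a proteome mapping is given, substitution annotations
    are checked against it.
    """
    required = PHOSPHO_COLUMNS if schema == "phospho" else PRECURSOR_COLUMNS
    frame = pd.read_csv(path, sep="\t")
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")

    reasons = pd.Series([None] * len(frame), index=frame.index, dtype=object)

    qcols = ["global_q"] + (
        ["peptidoform_q", "site_confidence"] if schema == "phospho" else []
    )
    for col in qcols:
        bad = ~frame[col].between(0, 1) | frame[col].isna()
        reasons[bad & reasons.isna()] = "bad_value"
    bad = (frame["intensity"] < 0) | (frame["start"] < 1)
    reasons[bad & reasons.isna()] = "bad_value"

    over = frame["global_q"] > max_q
    if schema == "phospho":
        over = over | (frame["peptidoform_q"] > max_q)
    reasons[over & reasons.isna()] = "q_filter"

    sub_pos = pd.Series(pd.NA, index=frame.index, dtype="Int64")
    sub_from = pd.Series(pd.NA, index=frame.index, dtype=object)
    sub_to = pd.Series(pd.NA, index=frame.index, dtype=object)
    for idx, row in frame.iterrows():
        if reasons[idx] is not None:
            continue
        try:
            base, subs, _mods = parse_modified_sequence(
                str(row["modified_sequence"])
            )
        except ValueError:
            reasons[idx] = "parse_error"
            continue
        if base != row["base_sequence"]:
            reasons[idx] = "parse_error"
            continue
        if len(subs) > 1:
            reasons[idx] = "parse_error"
            continue
        if subs:
            site = subs[0]
            start = int(row["start"])
            offset = site.position - start
            if not 0 <= offset < len(base):
                reasons[idx] = "inconsistent_substitution"
                continue
            if base[offset] != site.to_residue:
                reasons[idx] = "inconsistent_substitution"
                continue
            if proteome is not None:
                ref = proteome.get(row["protein_id"])
                if ref is None or len(ref) < site.position or ref[
                    site.position - 1
                ] != site.from_residue:
                    reasons[idx] = "inconsistent_substitution"
                    continue
            sub_pos[idx] = site.position
            sub_from[idx] = site.from_residue
            sub_to[idx] = site.to_residue

    frame = frame.assign(sub_pos=sub_pos, sub_from=sub_from, sub_to=sub_to)
    rejected = reasons.notna()
    rejects = frame[rejected].copy()
    rejects["reject_reason"] = reasons[rejected]
    accepted = frame[~rejected].copy()
    return accepted, rejects


# ---------------------------------------------------------------------------
# annotations and manifests

def read_kinase_substrates(path) -> pd.DataFrame:
    """Kinase-substrate annotation TSV with kinase, protein, site columns."""
    frame = pd.read_csv(path, sep="\t")
    missing = [c for c in ("kinase", "protein", "site") if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return frame


def read_rsa(path) -> pd.DataFrame:
    """Per-residue relative solvent accessibility TSV."""
    frame = pd.read_csv(path, sep="\t")
    missing = [
        c for c in ("protein_id", "position", "rsa") if c not in frame.columns
    ]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return frame


def read_run_manifest(path) -> dict:
    """YAML run manifest: strain -> replicate -> file, plus parameters."""
    with open(path) as fh:
        manifest = yaml.safe_load(fh)
    for strain, replicates in manifest.get("runs", {}).items():
        for replicate, file_path in replicates.items():
            if not Path(file_path).exists():
                raise FileNotFoundError(
                    f"manifest {strain}/{replicate}: {file_path} not found"
                )
    return manifest


def write_run_log(path, parameters: Mapping) -> None:
    """Persist the full parameter set of a run alongside its outputs."""
    from . import __version__

    payload = {"mistraq_version": __version__, "parameters": dict(parameters)}
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)
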