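"""Detection and characterization of phosphosites on misinserted serines.

A serine misinserted at a proline or arginine codon is a brand-new
phospho-acceptor.  Because a combined substitution+phospho identification
is easy to get wrong, retention is stringent: the site must be seen in
every replicate, its phosphate localization must be confident, and the
peptidoform must pass FDR.  Retained sites are then characterized by
positional motif enrichment around the new serine and by rank comparisons
(solvent accessibility, protein abundance) against canonical phosphosites.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

DEFAULT_MIN_LOCALIZATION = 0.75
DEFAULT_MAX_Q = 0.01
DEFAULT_WINDOW = 6
DEFAULT_ALPHA_MOTIF = 1e-6


@dataclass(frozen=True)
class PhosphoSiteObservation:
    """One phosphosite aggregated over a strain's replicates.

    ``origin`` is ``"canonical"`` for phospho on encoded S/T/Y and
    ``"misinserted"`` for phospho on a substitution-created serine.
    ``localization_confidence`` and ``peptidoform_q`` are the best values
    among the supporting peptidoforms; ``replicate_presence`` lists the
    replicates with at least one supporting passing peptidoform.
    """

    protein_id: str
    protein_position: int
    origin: str
    strain_id: str
    localization_confidence: float
    peptidoform_q: float
    replicate_presence: frozenset = frozenset()
    from_residue: Optional[str] = None

    @property
    def site_id(self) -> str:
        return f"{self.protein_id}:{self.protein_position}"


def collect_site_observations(
    report: pd.DataFrame,
    min_localization: float = DEFAULT_MIN_LOCALIZATION,
    max_q: float = DEFAULT_MAX_Q,
) -> list[PhosphoSiteObservation]:
    """Aggregate a phospho report into per-site observations.

    A row supports a site only if it individually passes the localization
    and peptidoform-q filters; replicate presence counts passing rows only.
    A row is misinserted-origin when its phospho position coincides with
    its substitution position.
    """
    rows = report[
        (report["site_confidence"] > min_localization)
        & (report["peptidoform_q"] <= max_q)
    ]
    grouped: dict[tuple, dict] = {}
    for row in rows.itertuples(index=False):
        pos = int(row.phospho_pos)
        misinserted = (not pd.isna(row.sub_pos)) and int(row.sub_pos) == pos
        origin = "misinserted" if misinserted else "canonical"
        key = (row.protein_id, pos, origin, row.strain_id)
        slot = grouped.setdefault(
            key,
            {
                "conf": 0.0,
                "q": 1.0,
                "reps": set(),
                "from": row.sub_from if misinserted else None,
            },
        )
        slot["conf"] = max(slot["conf"], float(row.site_confidence))
        slot["q"] = min(slot["q"], float(row.peptidoform_q))
        slot["reps"].add(row.replicate_id)
    return [
        PhosphoSiteObservation(
            protein_id=protein,
            protein_position=pos,
            origin=origin,
            strain_id=strain,
            localization_confidence=slot["conf"],
            peptidoform_q=slot["q"],
            replicate_presence=frozenset(slot["reps"]),
            from_residue=slot["from"],
        )
        for (protein, pos, origin, strain), slot in sorted(grouped.items())
    ]


def detect_novel_sites(
    observations: Iterable[PhosphoSiteObservation],
    n_replicates_required: int = 6,
    min_localization: float = DEFAULT_MIN_LOCALIZATION,
    max_q: float = DEFAULT_MAX_Q,
) -> list[PhosphoSiteObservation]:
    """Retain misinserted-serine phosphosites passing all three filters:
    presence in all required replicates, localization confidence above
    ``min_localization`` (strict), peptidoform q at or below ``max_q``."""
    return [
        obs
        for obs in observations
        if obs.origin == "misinserted"
        and len(obs.replicate_presence) >= n_replicates_required
        and obs.localization_confidence > min_localization
        and obs.peptidoform_q <= max_q
    ]


def _flank(proteome: Mapping[str, str], protein: str, pos: int, offset: int):
    seq = proteome[protein]
    i = pos - 1 + offset
    if 0 <= i < len(seq):
        return seq[i]
    return None


def motif_enrichment(
    sites: Sequence[Tuple[str, int]],
    proteome: Mapping[str, str],
    background_sites: Sequence[Tuple[str, int]],
    window_halfwidth: int = DEFAULT_WINDOW,
    alpha_motif: float = DEFAULT_ALPHA_MOTIF,
) -> pd.DataFrame:
    """Positional residue enrichment around phosphosites.

    For each offset in +-window (0 excluded: that is the phosphosite
    itself) and each residue seen there, the binomial upper-tail p-value of
    the foreground count against the background frequency at the same
    offset.  Sites near a protein terminus simply do not contribute to
    offsets that fall outside the sequence.  Background frequencies come
    from the flanking windows of ``background_sites`` (typically all
    quantified canonical phosphosites of the same dataset).
    """
    if not len(sites):
        return pd.DataFrame(
            columns=[
                "offset",
                "residue",
                "foreground_count",
                "foreground_n",
                "background_freq",
                "p",
                "enriched",
            ]
        )
    offsets = [
        o for o in range(-window_halfwidth, window_halfwidth + 1) if o != 0
    ]
    bg_counts: dict[int, dict[str, int]] = {o: {} for o in offsets}
    bg_n: dict[int, int] = {o: 0 for o in offsets}
    for protein, pos in background_sites:
        for o in offsets:
            aa = _flank(proteome, protein, pos, o)
            if aa is not None:
                bg_counts[o][aa] = bg_counts[o].get(aa, 0) + 1
                bg_n[o] += 1

    fg_counts: dict[int, dict[str, int]] = {o: {} for o in offsets}
    fg_n: dict[int, int] = {o: 0 for o in offsets}
    for protein, pos in sites:
        for o in offsets:
            aa = _flank(proteome, protein, pos, o)
            if aa is not None:
                fg_counts[o][aa] = fg_counts[o].get(aa, 0) + 1
                fg_n[o] += 1

    records = []
    for o in offsets:
        n = fg_n[o]
        for aa, k in sorted(fg_counts[o].items()):
            if bg_n[o] > 0:
                freq = bg_counts[o].get(aa, 0) / bg_n[o]
            else:
                freq = float("nan")
            if not np.isfinite(freq):
                p = float("nan")
            elif freq <= 0.0:
                p = 0.0 if k > 0 else 1.0
            else:
                p = float(sps.binom.sf(k - 1, n, freq))
            records.append(
                {
                    "offset": o,
                    "residue": aa,
                    "foreground_count": k,
                    "foreground_n": n,
                    "background_freq": freq,
                    "p": p,
                }
            )
    frame = pd.DataFrame.from_records(records)
    frame["enriched"] = frame["p"] < alpha_motif
    return frame


@dataclass
class RankCompareResult:
    p: float
    u: float
    direction: str  # "a_greater", "b_greater" or "none"
    method: str


def _exact_mannwhitney(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney by enumerating group assignments.

    Enumerates every way of splitting the pooled values into groups of the
    observed sizes; ties are handled through midranks of the actual pooled
    multiset.  Returns (U_a, p).
    """
    n, m = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    u_obs = float(ranks[:n].sum() - n * (n + 1) / 2)
    us = []
    for combo in itertools.combinations(range(n + m), n):
        us.append(float(ranks[list(combo)].sum() - n * (n + 1) / 2))
    us = np.asarray(us)
    total = len(us)
    p_le = np.sum(us <= u_obs + 1e-9) / total
    p_ge = np.sum(us >= u_obs - 1e-9) / total
    return u_obs, min(1.0, 2.0 * min(p_le, p_ge))


def rank_compare(
    values_a: Sequence[float], values_b: Sequence[float]
) -> RankCompareResult:
    """Two-sided Mann-Whitney comparison of two samples.

    Exact by full enumeration when the smaller sample has at most 8 values
    (and enumeration stays tractable); otherwise the normal approximation
    with tie correction and continuity correction.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    n, m = len(a), len(b)
    u_a = float(
        sps.rankdata(np.concatenate([a, b]))[:n].sum() - n * (n + 1) / 2
    )
    if u_a > n * m / 2:
        direction = "a_greater"
    elif u_a < n * m / 2:
        direction = "b_greater"
    else:
        direction = "none"

    if np.all(np.concatenate([a, b]) == a[0]):
        return RankCompareResult(1.0, u_a, "none", "degenerate")

    if min(n, m) <= 8 and math.comb(n + m, n) <= 200_000:
        u, p = _exact_mannwhitney(a, b)
        return RankCompareResult(p, u, direction, "exact")
    res = sps.mannwhitneyu(
        a, b, alternative="two-sided", method="asymptotic"
    )
    return RankCompareResult(float(res.pvalue), u_a, direction, "asymptotic")
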