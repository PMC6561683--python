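"""Proteome-wide motif statistics.

Grouping and combination breakdowns, the motif-count-vs-length regression,
positional distributions along the normalized protein length, amino-acid
position preferences inside the motif, and the scrambled-proteome
permutation baseline with subsampled t-tests.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.outliers_influence import OLSInfluence

from kferqscan.io import ProteinRecord
from kferqscan.motif_engine import (
    HIERARCHY,
    MotifClass,
    MotifMatch,
    Orientation,
    ProteinMotifSummary,
    scan_protein,
)

logger = logging.getLogger(__name__)

__all__ = [
    "GroupBreakdown",
    "LengthModelFit",
    "PositionHistogram",
    "PositionFrequencyTable",
    "BaselineComparison",
    "group_percentages",
    "combination_breakdown",
    "motifs_per_protein_histogram",
    "fit_length_model",
    "positional_distribution",
    "terminal_depletion",
    "aa_position_frequencies",
    "scramble_proteome",
    "baseline_comparison",
    "composition_comparison",
]

POSITIONS = (-4, -3, -2, -1)

#: Residues that can occupy the variable region, per motif class.
CLASS_ALPHABET = {
    MotifClass.CANONICAL: tuple("KRILVFDE"),
    MotifClass.ACETYL: tuple("KRILVFDE"),
    MotifClass.PHOSPHO: tuple("KRILVFSTY"),
}

GROUP_LABELS = ("canonical", "phospho_generated", "acetyl_generated", "none")


@dataclass
class GroupBreakdown:
    percentages: dict  # hierarchy group -> percent of proteins
    n_proteins: int


@dataclass
class LengthModelFit:
    slope: float
    intercept: float
    r_squared: float
    n_removed_outliers: int
    n_used: int


@dataclass
class PositionHistogram:
    bin_size: float
    bin_edges: np.ndarray
    counts: np.ndarray
    exclude_initiator_met: bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_start": self.bin_edges[:-1],
                "bin_end": self.bin_edges[1:],
                "count": self.counts,
            }
        )


@dataclass
class PositionFrequencyTable:
    """Per-amino-acid position preference inside one motif class.

    ``percentages`` holds, for each amino acid, the share of its
    occurrences at positions -4..-1 relative to the flank (each row sums
    to 100 when the amino acid occurs at all); ``property_percentages``
    aggregates the rows into basic/hydrophobic/acidic categories, with the
    phospho-acceptors S/T/Y counted as acidic for the phospho class.
    """

    motif_class: MotifClass
    counts: pd.DataFrame
    percentages: pd.DataFrame
    property_percentages: pd.DataFrame


@dataclass
class BaselineComparison:
    """Observed-vs-scrambled position frequencies over repeated subsamples."""

    ratio_mean: pd.DataFrame
    ratio_sd: pd.DataFrame
    t_statistic: pd.DataFrame
    p_corrected: pd.DataFrame
    n_replicates_used: int
    bonferroni_n: int


def group_percentages(summaries: Sequence[ProteinMotifSummary]) -> GroupBreakdown:
    """Percent of proteins per hierarchy group (canonical > phospho-generated
    > acetyl-generated > none)."""
    if not summaries:
        raise ValueError("empty proteome")
    n = len(summaries)
    pct = {g: 0.0 for g in GROUP_LABELS}
    for s in summaries:
        pct[s.hierarchy_group] += 1
    for g in pct:
        pct[g] = 100.0 * pct[g] / n
    return GroupBreakdown(percentages=pct, n_proteins=n)


def combination_breakdown(summaries: Sequence[ProteinMotifSummary]) -> dict:
    """Percent of proteins per combination of motif classes present.

    Partitions the proteome into the 8 subsets of
    {canonical, phospho_generated, acetyl_generated} (the empty signature
    being the motif-free proteins); percentages sum to 100.
    """
    if not summaries:
        raise ValueError("empty proteome")
    n = len(summaries)
    out: dict[frozenset, float] = {}
    for s in summaries:
        out[s.combination_signature] = out.get(s.combination_signature, 0.0) + 1
    return {sig: 100.0 * c / n for sig, c in out.items()}


def motifs_per_protein_histogram(
    summaries: Sequence[ProteinMotifSummary],
    motif_class: MotifClass | None = None,
) -> dict:
    """Histogram of motif counts per protein.

    With ``motif_class=None`` each protein contributes the count of its
    group-defining (highest-ranking) class, following the hierarchy; with a
    class given, only proteins whose hierarchy group is that class
    contribute, counting motifs of that class.
    """
    hist: dict[int, int] = {}
    for s in summaries:
        if s.hierarchy_group == "none":
            continue
        group_cls = MotifClass(s.hierarchy_group)
        if motif_class is not None and group_cls is not motif_class:
            continue
        k = s.counts[group_cls]
        hist[k] = hist.get(k, 0) + 1
    return hist


def fit_length_model(summaries: Sequence[ProteinMotifSummary]) -> LengthModelFit:
    """OLS regression of log2(canonical motif count) on protein length.

    Restricted to proteins with at least one canonical motif (log2 of zero
    is undefined).  After an initial fit, all points with Cook's distance
    above 1 are removed in a single pass and the model is refit once; the
    reported R^2 is that of the final fit.
    """
    pts = [(s.length, s.counts[MotifClass.CANONICAL]) for s in summaries
           if s.counts[MotifClass.CANONICAL] > 0]
    if len(pts) < 3:
        raise ValueError("need at least 3 proteins with a canonical motif")
    x = np.array([p[0] for p in pts], dtype=float)
    y = np.log2([p[1] for p in pts])
    if np.ptp(x) == 0:
        raise ValueError("degenerate regressor: all proteins have the same length")

    def _fit(xv, yv):
        X = sm.add_constant(xv)
        return sm.OLS(yv, X).fit()

    res = _fit(x, y)
    if res.ssr <= 1e-10:
        # (near-)exact fit: residuals are numerical noise and Cook's
        # distances are 0/0 garbage; nothing is an outlier
        cooks = np.zeros(len(x))
    else:
        cooks = OLSInfluence(res).cooks_distance[0]
    keep = ~(cooks > 1.0)  # NaN distance is not an outlier
    n_removed = int((~keep).sum())
    if n_removed:
        x, y = x[keep], y[keep]
        if np.ptp(x) == 0:
            raise ValueError("degenerate regressor after outlier removal")
        res = _fit(x, y)
    # a constant response has no variance to explain: R^2 is 0 by convention
    r2 = 0.0 if np.ptp(y) == 0 else float(res.rsquared)
    return LengthModelFit(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        r_squared=r2,
        n_removed_outliers=n_removed,
        n_used=len(x),
    )


def _relative_positions(
    matches: Iterable[MotifMatch],
    lengths: Mapping[str, int],
    exclude_initiator_met: bool = False,
    use_center: bool = True,
) -> np.ndarray:
    rel = []
    for m in matches:
        length = lengths[m.protein_id]
        pos = m.center if use_center else m.start
        if exclude_initiator_met:
            pos, length = pos - 1, length - 1
        rel.append(pos / length)
    return np.asarray(rel, dtype=float)


def positional_distribution(
    matches: Sequence[MotifMatch],
    lengths: Mapping[str, int],
    bin_size: float = 0.02,
    exclude_initiator_met: bool = False,
    use_center: bool = True,
) -> PositionHistogram:
    """Histogram of motif positions on the normalized 0 (N-terminus) to 1
    (C-terminus) scale.

    A motif's position is its central residue divided by the protein
    length (optionally discounting the initiator methionine from both).
    """
    rel = _relative_positions(matches, lengths, exclude_initiator_met, use_center)
    n_bins = int(round(1.0 / bin_size))
    counts, edges = np.histogram(rel, bins=n_bins, range=(0.0, 1.0))
    return PositionHistogram(
        bin_size=bin_size,
        bin_edges=edges,
        counts=counts,
        exclude_initiator_met=exclude_initiator_met,
    )


def terminal_depletion(
    matches: Sequence[MotifMatch],
    lengths: Mapping[str, int],
    head_fraction: float = 0.025,
) -> float:
    """Percent depletion of motif density in the N-terminal head of proteins.

    Compares motif density (motifs per unit relative length) in the first
    ``head_fraction`` of the normalized length against the remainder and
    returns ``100 * (1 - head_density / tail_density)``: positive values
    mean fewer motifs near the N-terminus.  NaN (with a warning) if the
    tail holds no motifs.
    """
    if not matches:
        raise ValueError("no motifs supplied")
    rel = _relative_positions(matches, lengths)
    n_head = int((rel < head_fraction).sum())
    n_tail = len(rel) - n_head
    if n_tail == 0:
        logger.warning("terminal_depletion: no motifs outside the head region; undefined")
        return math.nan
    head_density = n_head / head_fraction
    tail_density = n_tail / (1.0 - head_fraction)
    return 100.0 * (1.0 - head_density / tail_density)


def _oriented_variable(m: MotifMatch) -> str:
    """Variable region read so index 0 is position -4 (furthest from the
    flank) and index 3 is position -1; Q-left motifs are mirrored."""
    if m.orientation is Orientation.Q_RIGHT:
        return m.pentapeptide[:4]
    return m.pentapeptide[:0:-1]


def position_count_table(matches: Sequence[MotifMatch], motif_class: MotifClass) -> pd.DataFrame:
    """Raw residue counts per (amino acid, position) for one motif class."""
    alphabet = CLASS_ALPHABET[motif_class.main_class]
    counts = pd.DataFrame(0, index=list(alphabet), columns=list(POSITIONS), dtype=float)
    for m in matches:
        if m.motif_class is not motif_class:
            raise ValueError("matches of a single class expected")
        var = _oriented_variable(m)
        for pos, aa in zip(POSITIONS, var):
            counts.loc[aa, pos] += 1
    return counts


def aa_position_frequencies(
    matches: Sequence[MotifMatch],
    motif_class: MotifClass,
) -> PositionFrequencyTable:
    """Position preference of each amino acid inside motifs of one class.

    Motifs are aligned on a downstream flank (Q-left motifs mirrored);
    positions are numbered -1 (next to the flank) to -4 (furthest away).
    Each amino-acid row is normalized as the percentage of that amino
    acid's total count over the four positions.
    """
    counts = position_count_table(matches, motif_class)
    row_tot = counts.sum(axis=1)
    percentages = counts.div(row_tot.where(row_tot > 0), axis=0) * 100.0

    rules_acidic = "STY" if motif_class.main_class is MotifClass.PHOSPHO else "DE"
    groups = {
        "basic": list("KR"),
        "hydrophobic": list("ILVF"),
        "acidic": list(rules_acidic),
    }
    prop_counts = pd.DataFrame(
        {pos: [counts.loc[res, pos].sum() for res in groups.values()] for pos in POSITIONS},
        index=list(groups),
    )
    prop_tot = prop_counts.sum(axis=1)
    prop_pct = prop_counts.div(prop_tot.where(prop_tot > 0), axis=0) * 100.0
    return PositionFrequencyTable(
        motif_class=motif_class,
        counts=counts,
        percentages=percentages,
        property_percentages=prop_pct,
    )


def scramble_proteome(
    records: Sequence[ProteinRecord],
    seed: int | np.random.Generator = 0,
) -> list[ProteinRecord]:
    """Independently permute each protein sequence (uniform shuffle).

    Per-protein amino-acid composition is exactly preserved; the same seed
    always yields the same scrambled proteome.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = []
    for rec in records:
        letters = np.array(list(rec.sequence))
        rng.shuffle(letters)
        out.append(
            ProteinRecord(
                accession=rec.accession,
                entry_name=rec.entry_name,
                status=rec.status,
                protein_names=rec.protein_names,
                gene_name=rec.gene_name,
                organism=rec.organism,
                sequence="".join(letters),
            )
        )
    return out


def baseline_comparison(
    records: Sequence[ProteinRecord],
    motif_class: MotifClass = MotifClass.CANONICAL,
    seed: int = 0,
    n_subsamples: int = 40,
    subsample_fraction: float = 0.10,
) -> BaselineComparison:
    """Compare motif position frequencies against a scrambled-proteome null.

    The proteome is scanned as-is and after per-protein sequence
    scrambling.  For each of ``n_subsamples`` replicates a fraction of the
    proteins is sampled without replacement from both sets and the
    per-cell (amino acid x position) frequency tables computed; the
    reported ratio is observed/scrambled per replicate, summarized by mean
    and standard deviation.  Per cell, a two-sided Welch t-test compares
    the observed and scrambled frequency samples, with Bonferroni
    correction by the number of cells (32 for an 8-residue alphabet).
    Replicates whose subsample holds no motif are dropped with a warning.
    """
    rng = np.random.default_rng(seed)
    scrambled = scramble_proteome(records, rng)

    def _per_protein(table: Sequence[ProteinRecord]):
        per = []
        for rec in table:
            hits = [m for m in scan_protein(rec.sequence, rec.accession)
                    if m.motif_class is motif_class]
            per.append(hits)
        return per

    obs_hits = _per_protein(records)
    scr_hits = _per_protein(scrambled)

    n = len(records)
    k = max(1, int(round(subsample_fraction * n)))
    alphabet = CLASS_ALPHABET[motif_class.main_class]

    def _freq(matches):
        counts = position_count_table(matches, motif_class)
        total = counts.values.sum()
        return counts / total * 100.0 if total > 0 else None

    obs_freqs, scr_freqs = [], []
    for _ in range(n_subsamples):
        idx_o = rng.choice(n, size=k, replace=False)
        idx_s = rng.choice(n, size=k, replace=False)
        fo = _freq([m for i in idx_o for m in obs_hits[i]])
        fs = _freq([m for i in idx_s for m in scr_hits[i]])
        if fo is None or fs is None:
            logger.warning("baseline_comparison: replicate with zero motifs dropped")
            continue
        obs_freqs.append(fo)
        scr_freqs.append(fs)
    if len(obs_freqs) < 2:
        raise ValueError("fewer than 2 usable replicates; increase proteome or fraction")

    obs_arr = np.stack([f.values for f in obs_freqs])  # (reps, aa, pos)
    scr_arr = np.stack([f.values for f in scr_freqs])
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = np.where(scr_arr > 0, obs_arr / scr_arr, np.nan)
    ratio_mean = np.nanmean(ratios, axis=0)
    ratio_sd = np.nanstd(ratios, axis=0, ddof=1)
    t_stat, p_val = stats.ttest_ind(obs_arr, scr_arr, axis=0, equal_var=False)

    n_cells = len(alphabet) * len(POSITIONS)
    p_corr = np.minimum(p_val * n_cells, 1.0)

    idx, cols = list(alphabet), list(POSITIONS)
    return BaselineComparison(
        ratio_mean=pd.DataFrame(ratio_mean, index=idx, columns=cols),
        ratio_sd=pd.DataFrame(ratio_sd, index=idx, columns=cols),
        t_statistic=pd.DataFrame(t_stat, index=idx, columns=cols),
        p_corrected=pd.DataFrame(p_corr, index=idx, columns=cols),
        n_replicates_used=len(obs_freqs),
        bonferroni_n=n_cells,
    )


def composition_comparison(
    records: Sequence[ProteinRecord],
    summaries: Sequence[ProteinMotifSummary],
) -> pd.DataFrame:
    """Amino-acid composition of motif-bearing vs motif-free proteins.

    Returns a two-row table (``with_motif``, ``without_motif``) of percent
    composition over the 20 standard residues; each row sums to 100.
    """
    groups = {s.protein_id: s.hierarchy_group != "none" for s in summaries}
    aas = sorted("ACDEFGHIKLMNPQRSTVWY")
    tallies = {True: dict.fromkeys(aas, 0), False: dict.fromkeys(aas, 0)}
    for rec in records:
        pool = tallies[groups[rec.accession]]
        for aa in rec.sequence:
            if aa in pool:
                pool[aa] += 1
    rows = {}
    for label, has in (("with_motif", True), ("without_motif", False)):
        tot = sum(tallies[has].values())
        rows[label] = {aa: (100.0 * c / tot if tot else 0.0) for aa, c in tallies[has].items()}
    return pd.DataFrame.from_dict(rows, orient="index")[aas]
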