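"""Solvent-accessibility profiling around motifs.

Consumes per-residue relative solvent accessibility (RSA) tracks produced
by a secondary-structure predictor or derived from structures, applies the
standard burial call (RSA < 0.25 => buried), and computes motif-centered
exposure profiles over a +/-30 residue window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from kferqscan.io import ProteinRecord
from kferqscan.motif_engine import MotifMatch

logger = logging.getLogger(__name__)

__all__ = [
    "BURIED_RSA_THRESHOLD",
    "ExposureTrack",
    "ExposureProfile",
    "read_rsa_tracks",
    "filter_length",
    "motif_exposure_profile",
]

#: Residues with relative solvent accessibility below this are buried.
BURIED_RSA_THRESHOLD = 0.25


@dataclass
class ExposureTrack:
    """Per-residue solvent accessibility for one protein."""

    protein_id: str
    rsa: np.ndarray  # float RSA in [0,1], or 0/1 exposure calls
    source: str = "predicted"

    def __len__(self) -> int:
        return len(self.rsa)

    @property
    def exposed(self) -> np.ndarray:
        """Boolean exposure calls; a residue is buried iff RSA < 0.25."""
        return self.rsa >= BURIED_RSA_THRESHOLD


@dataclass
class ExposureProfile:
    """Percent-exposed curve at offsets around the motif center."""

    offsets: np.ndarray  # -window .. +window
    pct_exposed: np.ndarray
    n_contributing: np.ndarray
    baseline: float  # mean % exposed over all residues of all proteins in scope

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "offset": self.offsets,
                "pct_exposed": self.pct_exposed,
                "n": self.n_contributing,
                "baseline": self.baseline,
            }
        )


def read_rsa_tracks(
    path,
    lengths: Mapping[str, int] | None = None,
    source: str = "predicted",
) -> dict[str, ExposureTrack]:
    """Read per-residue RSA tracks from a TSV.

    Expected columns: ``protein_id``, ``position`` (1-based) and ``rsa``
    (real in [0,1]) or ``exposed`` (0/1).  Each protein's rows must cover
    positions 1..L exactly once; when ``lengths`` is given, track lengths
    are validated against it and mismatches raise an error naming the
    protein.
    """
    df = pd.read_csv(path, sep="\t")
    value_col = "rsa" if "rsa" in df.columns else "exposed"
    if value_col not in df.columns or not {"protein_id", "position"} <= set(df.columns):
        raise ValueError(f"{path}: need columns protein_id, position, and rsa or exposed")
    tracks: dict[str, ExposureTrack] = {}
    for pid, sub in df.groupby("protein_id", sort=False):
        sub = sub.sort_values("position")
        pos = sub["position"].to_numpy()
        if not np.array_equal(pos, np.arange(1, len(pos) + 1)):
            raise ValueError(f"protein {pid}: positions must be contiguous 1..L")
        vals = sub[value_col].to_numpy(dtype=float)
        if ((vals < 0) | (vals > 1)).any():
            raise ValueError(f"protein {pid}: RSA values outside [0,1]")
        if lengths is not None and pid in lengths and lengths[pid] != len(vals):
            raise ValueError(
                f"protein {pid}: track length {len(vals)} != sequence length {lengths[pid]}"
            )
        tracks[str(pid)] = ExposureTrack(protein_id=str(pid), rsa=vals, source=source)
    return tracks


def filter_length(
    records: Sequence[ProteinRecord],
    max_len: int = 800,
) -> list[ProteinRecord]:
    """Drop proteins longer than ``max_len`` residues.

    Sequence-based accessibility predictors commonly cap input length (800
    residues for JPred4-style predictors); proteins above the cap are
    removed rather than truncated.
    """
    kept = [r for r in records if r.length <= max_len]
    dropped = len(records) - len(kept)
    if dropped:
        logger.info("filter_length: dropped %d protein(s) longer than %d aa", dropped, max_len)
    return kept


def motif_exposure_profile(
    matches: Sequence[MotifMatch],
    tracks: Mapping[str, ExposureTrack],
    window: int = 30,
) -> ExposureProfile:
    """Percent of exposed residues at each offset around motif centers.

    Every motif whose protein has a track contributes one +/-``window``
    residue alignment centered on its central residue; offsets falling
    outside the protein are skipped (they shrink the denominator rather
    than being padded).  The baseline is the percent of exposed residues
    over *all* residues of all proteins in scope (every protein with a
    track), matching the interpretation of exposure as a whole-dataset
    background rate.
    """
    if not matches:
        raise ValueError("no motifs supplied")
    offsets = np.arange(-window, window + 1)
    exposed_ct = np.zeros(len(offsets), dtype=int)
    total_ct = np.zeros(len(offsets), dtype=int)
    n_used = 0
    for m in matches:
        track = tracks.get(m.protein_id)
        if track is None:
            continue
        n_used += 1
        calls = track.exposed
        c = m.center - 1  # 0-based center
        for j, off in enumerate(offsets):
            i = c + off
            if 0 <= i < len(calls):
                total_ct[j] += 1
                exposed_ct[j] += bool(calls[i])
    if n_used == 0:
        raise ValueError("no match has a matching RSA track")
    with np.errstate(invalid="ignore"):
        pct = np.where(total_ct > 0, 100.0 * exposed_ct / np.maximum(total_ct, 1), np.nan)

    all_exposed = all_total = 0
    for track in tracks.values():
        all_exposed += int(track.exposed.sum())
        all_total += len(track)
    baseline = 100.0 * all_exposed / all_total
    return ExposureProfile(
        offsets=offsets,
        pct_exposed=pct,
        n_contributing=total_ct,
        baseline=baseline,
    )
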