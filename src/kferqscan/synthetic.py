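"""Seeded synthetic data with recorded ground truth.

Generators for proteomes with planted motifs, ortholog families with
controlled per-group motif retention, annotation tables with planted
enrichment, and RSA tracks with elevated exposure at motif offsets.  Every
generator is deterministic under a fixed seed and re-validates its own
output against the modules it feeds (a planted motif must be re-detected
by the scanner before the proteome is returned).

These fixtures emulate the statistical structure the analyses rely on
(motif classes and positions, per-group retention, relative-risk
enrichment, exposure rates); they do not emulate real protein features
such as domain structure, repeat content or phylogenetic correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from kferqscan.conservation import OrthologFamily
from kferqscan.exposure import BURIED_RSA_THRESHOLD, ExposureTrack
from kferqscan.io import ProteinRecord
from kferqscan.motif_engine import (
    MotifClass,
    MotifMatch,
    Orientation,
    classify_window,
    scan_protein,
)

__all__ = [
    "PlantedMotif",
    "ProteomeGroundTruth",
    "sample_motif",
    "make_proteome",
    "make_ortholog_families",
    "make_annotations",
    "make_rsa_tracks",
    "tracks_to_tsv",
    "annotations_to_tsv",
]

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class PlantedMotif:
    protein_id: str
    motif_class: MotifClass
    start: int  # 1-based
    pentapeptide: str
    orientation: Orientation


@dataclass
class ProteomeGroundTruth:
    """What the generator wrote, and what the scanner additionally found."""

    planted: list = field(default_factory=list)  # PlantedMotif
    incidental: list = field(default_factory=list)  # chance MotifMatch from background

    def planted_for(self, protein_id: str) -> list:
        return [p for p in self.planted if p.protein_id == protein_id]


_FLANKS = {
    MotifClass.CANONICAL: "Q",
    MotifClass.PHOSPHO: "Q",
    MotifClass.ACETYL: "K",
    MotifClass.N_CANONICAL: "N",
    MotifClass.N_PHOSPHO: "N",
}


def sample_motif(
    motif_class: MotifClass,
    rng: np.random.Generator,
    orientation: Orientation | None = None,
) -> tuple[str, Orientation]:
    """Draw a uniformly random valid pentapeptide of the requested class.

    The variable region is built from 1-2 basic, 1-2 hydrophobic and one
    acidic-slot residue (D/E, or S/T/Y for the phospho classes), shuffled,
    with the class's flank residue attached on the sampled side.  The
    result is validated with :func:`classify_window` before being returned.
    """
    if motif_class not in _FLANKS:
        raise ValueError(f"cannot plant motifs of class {motif_class}")
    acidic_pool = "STY" if motif_class.main_class is MotifClass.PHOSPHO else "DE"
    n_basic = int(rng.integers(1, 3))
    n_hydro = 3 - n_basic
    letters = (
        list(rng.choice(list("KR"), size=n_basic))
        + list(rng.choice(list("ILVF"), size=n_hydro))
        + [str(rng.choice(list(acidic_pool)))]
    )
    rng.shuffle(letters)
    if orientation is None:
        orientation = Orientation(rng.choice([o.value for o in Orientation]))
    flank = _FLANKS[motif_class]
    if orientation is Orientation.Q_RIGHT:
        penta = "".join(letters) + flank
    else:
        penta = flank + "".join(letters)
    advanced = motif_class.is_n_class
    hits = classify_window(penta, advanced_n=advanced)
    assert (motif_class, orientation) in hits, f"generator produced invalid motif {penta!r}"
    return penta, orientation


def _background_sampler(
    background_frequencies: Mapping[str, float] | None,
    exclude: str = "",
):
    if background_frequencies is None:
        alphabet = [a for a in STANDARD_AA if a not in exclude]
        probs = np.full(len(alphabet), 1.0 / len(alphabet))
    else:
        alphabet = [a for a in sorted(background_frequencies) if a not in exclude]
        probs = np.array([background_frequencies[a] for a in alphabet], dtype=float)
        if probs.sum() <= 0:
            raise ValueError("background frequencies must have positive mass")
        probs = probs / probs.sum()
    alphabet_arr = np.array(alphabet)

    def draw(n: int, rng: np.random.Generator) -> str:
        return "".join(rng.choice(alphabet_arr, size=n, p=probs))

    return draw


def _place_starts(length: int, n_motifs: int, rng: np.random.Generator,
                  min_spacing: int = 5, max_tries: int = 200) -> list[int]:
    """Sample 0-based window starts so planted windows are separated by at
    least ``min_spacing`` residues (no merging)."""
    if n_motifs == 0:
        return []
    if length < n_motifs * (5 + min_spacing) - min_spacing:
        raise ValueError(f"protein of length {length} cannot hold {n_motifs} spaced motifs")
    for _ in range(max_tries):
        starts = sorted(rng.choice(length - 4, size=n_motifs, replace=False))
        if all(b - a >= 5 + min_spacing for a, b in zip(starts, starts[1:])):
            return starts
    raise RuntimeError("could not place planted motifs; lengthen the protein")


def make_proteome(
    n_proteins: int = 100,
    length_range: tuple = (120, 400),
    planted: Mapping[MotifClass, int] | Sequence[Mapping[MotifClass, int]] | None = None,
    background_frequencies: Mapping[str, float] | None = None,
    exclude_from_background: str = "",
    seed: int = 0,
    id_prefix: str = "SYN",
) -> tuple[list[ProteinRecord], ProteomeGroundTruth]:
    """Generate a synthetic proteome with planted motifs of known classes.

    ``planted`` is either one class->count mapping applied to every
    protein or a sequence of per-protein mappings (cycled over the
    proteome).  Background residues are drawn i.i.d. (uniform over the 20
    standard residues by default, or from an empirical composition);
    ``exclude_from_background`` removes letters from the background
    alphabet, e.g. ``"QKN"`` to suppress chance flanks entirely.  Planted
    windows overwrite background residues at starts spaced at least 5
    residues apart.  The generator re-scans its output and asserts every
    planted motif is detected; chance motifs arising from the background
    are recorded separately as ``incidental``.
    """
    if n_proteins <= 0:
        raise ValueError("n_proteins must be positive")
    rng = np.random.default_rng(seed)
    draw = _background_sampler(background_frequencies, exclude_from_background)
    if planted is None:
        plans: list[Mapping[MotifClass, int]] = [{}] * n_proteins
    elif isinstance(planted, Mapping):
        plans = [planted] * n_proteins
    else:
        plans = [planted[i % len(planted)] for i in range(n_proteins)]

    records: list[ProteinRecord] = []
    truth = ProteomeGroundTruth()
    for i in range(n_proteins):
        pid = f"{id_prefix}{i:05d}"
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        plan = plans[i]
        n_motifs = sum(plan.values())
        if length < 5 and n_motifs:
            raise ValueError("protein too short to hold a motif")
        seq = list(draw(length, rng))
        starts = _place_starts(length, n_motifs, rng)
        slots = iter(starts)
        planted_here = []
        for cls, count in plan.items():
            for _ in range(count):
                start0 = next(slots)
                penta, orient = sample_motif(cls, rng)
                seq[start0 : start0 + 5] = list(penta)
                planted_here.append(
                    PlantedMotif(pid, cls, start0 + 1, penta, orient)
                )
        sequence = "".join(seq)
        records.append(
            ProteinRecord(
                accession=pid, entry_name=f"{pid}_SYN", status="Swiss-Prot",
                protein_names="synthetic protein", gene_name=pid,
                organism="synthetic", sequence=sequence,
            )
        )
        # generation-time self-check: every planted motif must be re-detected
        advanced = any(p.motif_class.is_n_class for p in planted_here)
        matches = scan_protein(sequence, pid, advanced_n=advanced)
        found = {(m.start, m.motif_class, m.orientation) for m in matches}
        for p in planted_here:
            assert (p.start, p.motif_class, p.orientation) in found, (
                f"planted motif {p} not recovered by the scanner"
            )
        truth.planted.extend(planted_here)
        planted_keys = {(p.start, p.motif_class, p.orientation) for p in planted_here}
        truth.incidental.extend(
            m for m in matches
            if (m.start, m.motif_class, m.orientation) not in planted_keys
        )
    return records, truth


def make_ortholog_families(
    n_families: int,
    species_table: Mapping[str, bool],
    retention: Mapping[bool, float],
    p_partial: float = 0.25,
    p_no_ortholog: float = 0.25,
    length: int = 80,
    seed: int = 0,
) -> tuple[list[OrthologFamily], pd.DataFrame]:
    """Simulate ortholog families with controlled per-group motif retention.

    Each family has a human sequence with one canonical motif.  Every
    species copies the human sequence and then, with probability
    ``1 - retention[group]`` (group = its CMA-able flag), loses the exact
    motif: with probability ``p_partial`` the flanking Q is swapped to K
    (an acetylation-generated motif, classified partial), with
    ``p_no_ortholog`` the species row is dropped entirely, and otherwise
    the acidic residue is substituted by glycine, destroying the motif
    (absent).  Alignments are gapless by construction.

    Returns the families and a per-family, per-species ground-truth table
    with columns family, species, cma_able, outcome.
    """
    for g, p in retention.items():
        if not 0 <= p <= 1:
            raise ValueError("retention probabilities must be in [0,1]")
    if p_partial + p_no_ortholog > 1:
        raise ValueError("p_partial + p_no_ortholog must not exceed 1")
    rng = np.random.default_rng(seed)
    draw = _background_sampler(None, exclude="QKN")
    families, truth_rows = [], []
    for f in range(n_families):
        human_id = f"HUM{f:05d}"
        penta, orient = sample_motif(MotifClass.CANONICAL, rng)
        start0 = int(rng.integers(0, length - 4))
        seq = list(draw(length, rng))
        seq[start0 : start0 + 5] = list(penta)
        human_seq = "".join(seq)
        motif = MotifMatch(
            protein_id=human_id, start=start0 + 1, pentapeptide=penta,
            orientation=orient, motif_class=MotifClass.CANONICAL,
        )
        aligned = {"human": human_seq}
        flank_idx = start0 + (4 if orient is Orientation.Q_RIGHT else 0)
        var_idx = [start0 + j for j in range(5) if start0 + j != flank_idx]
        acidic_idx = next(i for i in var_idx if human_seq[i] in "DE")
        for sp, able in species_table.items():
            u = rng.random()
            if u < retention[able]:
                aligned[sp] = human_seq
                outcome = "conserved"
            else:
                v = rng.random()
                if v < p_no_ortholog:
                    outcome = "no_ortholog"
                elif v < p_no_ortholog + p_partial:
                    row = list(human_seq)
                    row[flank_idx] = "K"
                    aligned[sp] = "".join(row)
                    outcome = "partial"
                else:
                    row = list(human_seq)
                    row[acidic_idx] = "G"
                    aligned[sp] = "".join(row)
                    outcome = "absent_motif"
            truth_rows.append(
                {"family": human_id, "species": sp, "cma_able": able, "outcome": outcome}
            )
        families.append(OrthologFamily(human_id=human_id, human_motif=motif, aligned=aligned))
    return families, pd.DataFrame(truth_rows)


def make_annotations(
    groups: Mapping[str, str],
    planted: Sequence[tuple] = (),
    n_background_terms: int = 10,
    term_size: int = 20,
    seed: int = 0,
) -> tuple[dict[str, set], pd.DataFrame]:
    """Generate an annotation table with optionally planted enrichment.

    ``groups`` maps protein id -> group label.  Background terms annotate
    ``term_size`` proteins drawn uniformly; each planted ``(term, group,
    relative_risk)`` triple draws with sampling weight ``relative_risk``
    for proteins of the target group and 1 for the rest (relative risk 1
    reduces to the null).  Returns the term->protein map and a
    ground-truth table.
    """
    if term_size <= 0:
        raise ValueError("term_size must be positive")
    rng = np.random.default_rng(seed)
    proteins = np.array(sorted(groups))
    if term_size > len(proteins):
        raise ValueError("term_size larger than the proteome")
    annotations: dict[str, set] = {}
    truth_rows = []
    for t in range(n_background_terms):
        term = f"BG{t:04d}"
        members = rng.choice(proteins, size=term_size, replace=False)
        annotations[term] = set(members)
        truth_rows.append({"term": term, "target_group": None, "relative_risk": 1.0})
    for term, target_group, rr in planted:
        if rr <= 0:
            raise ValueError("relative risk must be positive")
        w = np.array([rr if groups[p] == target_group else 1.0 for p in proteins])
        members = rng.choice(proteins, size=term_size, replace=False, p=w / w.sum())
        annotations[term] = set(members)
        truth_rows.append({"term": term, "target_group": target_group, "relative_risk": rr})
    return annotations, pd.DataFrame(truth_rows)


def make_rsa_tracks(
    records: Sequence[ProteinRecord],
    matches: Sequence[MotifMatch] = (),
    baseline_rate: float = 0.5,
    boost_offsets: Sequence[int] = (),
    boosted_rate: float = 0.9,
    seed: int = 0,
) -> dict[str, ExposureTrack]:
    """Bernoulli exposure tracks with optional boosts at motif offsets.

    Every residue is exposed with ``baseline_rate``; residues at the given
    offsets from any motif center are instead exposed with
    ``boosted_rate``.  Exposure calls are encoded as RSA 0.0 (buried) /
    1.0 (exposed), consistent with the < 0.25 burial threshold.
    """
    for rate in (baseline_rate, boosted_rate):
        if not 0 <= rate <= 1:
            raise ValueError("rates must be in [0,1]")
    rng = np.random.default_rng(seed)
    by_protein: dict[str, list[int]] = {}
    for m in matches:
        by_protein.setdefault(m.protein_id, []).append(m.center - 1)
    tracks = {}
    for rec in records:
        exposed = rng.random(rec.length) < baseline_rate
        for center in by_protein.get(rec.accession, []):
            for off in boost_offsets:
                i = center + off
                if 0 <= i < rec.length:
                    exposed[i] = rng.random() < boosted_rate
        tracks[rec.accession] = ExposureTrack(
            protein_id=rec.accession, rsa=exposed.astype(float), source="synthetic"
        )
    return tracks


def tracks_to_tsv(tracks: Mapping[str, ExposureTrack], path) -> None:
    """Write tracks in the TSV contract consumed by the exposure module."""
    with open(path, "w") as fh:
        fh.write("protein_id\tposition\trsa\n")
        for pid in sorted(tracks):
            for i, v in enumerate(tracks[pid].rsa, start=1):
                fh.write(f"{pid}\t{i}\t{v:g}\n")


def annotations_to_tsv(annotations: Mapping[str, set], path) -> None:
    with open(path, "w") as fh:
        fh.write("term_id\tprotein_id\n")
        for term in sorted(annotations):
            for pid in sorted(annotations[term]):
                fh.write(f"{term}\t{pid}\n")
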