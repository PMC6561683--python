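"""Proteome-wide summaries: grouping, regression, positions, permutation baseline."""

import math

import numpy as np
import pandas as pd
import pytest

from kferqscan.motif_engine import (
    MotifClass,
    MotifMatch,
    Orientation,
    scan_protein,
    summarize_protein,
)
from kferqscan import proteome_stats as ps
from kferqscan.synthetic import make_proteome


def _summary(pid, length, canonical=0, phospho=0, acetyl=0):
    counts = {c: 0 for c in MotifClass}
    counts[MotifClass.CANONICAL] = canonical
    counts[MotifClass.PHOSPHO] = phospho
    counts[MotifClass.ACETYL] = acetyl
    group = "none"
    for cls in (MotifClass.CANONICAL, MotifClass.PHOSPHO, MotifClass.ACETYL):
        if counts[cls]:
            group = cls.value
            break
    sig = frozenset(
        c.value
        for c in (MotifClass.CANONICAL, MotifClass.PHOSPHO, MotifClass.ACETYL)
        if counts[c]
    )
    total = canonical + phospho + acetyl
    frac = tuple(100.0 * x / total for x in (canonical, phospho, acetyl)) if total else None
    from kferqscan.motif_engine import ProteinMotifSummary

    return ProteinMotifSummary(pid, length, counts, group, sig, frac)


def _match(pid, start, cls=MotifClass.CANONICAL, penta="KFERQ", orient=Orientation.Q_RIGHT):
    return MotifMatch(pid, start, penta, orient, cls)


class TestGrouping:
    def test_group_percentages_examples(self):
        summaries = [
            _summary("a", 100, canonical=1),
            _summary("b", 100, canonical=2),
            _summary("c", 100),
            _summary("d", 100, acetyl=1),
        ]
        b = ps.group_percentages(summaries)
        assert b.percentages == {
            "canonical": 50.0,
            "phospho_generated": 0.0,
            "acetyl_generated": 25.0,
            "none": 25.0,
        }
        assert b.n_proteins == 4

    def test_all_none(self):
        b = ps.group_percentages([_summary("a", 10), _summary("b", 10)])
        assert b.percentages["none"] == 100.0

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            ps.group_percentages([])

    def test_planted_fixture_recovers_exact_fractions(self):
        plans = [
            {MotifClass.CANONICAL: 1},
            {MotifClass.PHOSPHO: 1},
            {MotifClass.ACETYL: 1},
            {},
        ]
        records, _ = make_proteome(
            n_proteins=40, planted=plans, exclude_from_background="QKN", seed=3
        )
        summaries = [
            summarize_protein(scan_protein(r.sequence, r.accession), r.accession, r.length)
            for r in records
        ]
        b = ps.group_percentages(summaries)
        # chance flanks are excluded from the background, and planted motif
        # residues cannot seed an unplanted flank for the canonical/phospho
        # groups, but a planted window's own K can create extra acetyl hits;
        # those never change the hierarchy group of a motif-bearing protein.
        assert b.percentages["canonical"] == 25.0
        assert b.percentages["phospho_generated"] == 25.0

    def test_combination_breakdown_partitions(self):
        summaries = [
            _summary("a", 10, canonical=1, phospho=1, acetyl=1),
            _summary("b", 10, canonical=1),
            _summary("c", 10),
        ]
        combos = ps.combination_breakdown(summaries)
        assert math.isclose(sum(combos.values()), 100.0)
        assert combos[frozenset({"canonical", "phospho_generated", "acetyl_generated"})] == pytest.approx(100 / 3)
        assert combos[frozenset()] == pytest.approx(100 / 3)

    def test_groups_consistent_with_combinations(self):
        records, _ = make_proteome(
            n_proteins=60,
            planted=[{MotifClass.CANONICAL: 1}, {MotifClass.CANONICAL: 1, MotifClass.PHOSPHO: 1}, {}],
            seed=11,
        )
        summaries = [
            summarize_protein(scan_protein(r.sequence, r.accession), r.accession, r.length)
            for r in records
        ]
        b = ps.group_percentages(summaries)
        combos = ps.combination_breakdown(summaries)
        with_canonical = sum(p for sig, p in combos.items() if "canonical" in sig)
        assert with_canonical == pytest.approx(b.percentages["canonical"])

    def test_motifs_per_protein_histogram(self):
        summaries = [
            _summary("a", 10, canonical=1),
            _summary("b", 10, canonical=1),
            _summary("c", 10, canonical=2),
            _summary("d", 10),
        ]
        assert ps.motifs_per_protein_histogram(summaries, MotifClass.CANONICAL) == {1: 2, 2: 1}
        assert ps.motifs_per_protein_histogram(summaries, MotifClass.ACETYL) == {}


class TestLengthModel:
    def test_noise_free_log2_linear_gives_r2_one(self):
        # exact powers of two so log2(count) is exactly linear in length
        summaries = [
            _summary(f"p{i}", 100 * (i + 1), canonical=2 ** i) for i in range(6)
        ]
        fit = ps.fit_length_model(summaries)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.n_removed_outliers == 0
        assert fit.slope == pytest.approx(1 / 100)

    def test_constant_counts_give_r2_zero(self):
        summaries = [_summary(f"p{i}", 100 + 50 * i, canonical=4) for i in range(8)]
        fit = ps.fit_length_model(summaries)
        assert fit.r_squared == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_lengths_raise(self):
        summaries = [_summary(f"p{i}", 200, canonical=i + 1) for i in range(5)]
        with pytest.raises(ValueError):
            ps.fit_length_model(summaries)

    def test_zero_count_proteins_excluded(self):
        summaries = [_summary(f"p{i}", 100 * (i + 1), canonical=2 ** i) for i in range(4)]
        summaries.append(_summary("z", 5000, canonical=0))
        fit = ps.fit_length_model(summaries)
        assert fit.n_used == 4

    def test_outlier_removed_by_cooks_distance(self):
        rng = np.random.default_rng(0)
        lengths = rng.integers(100, 1000, size=40)
        counts = np.maximum(1, np.round(2 ** (0.002 * lengths + rng.normal(0, 0.2, 40)))).astype(int)
        summaries = [
            _summary(f"p{i}", int(l), canonical=int(c)) for i, (l, c) in enumerate(zip(lengths, counts))
        ]
        # one extreme high-leverage point
        summaries.append(_summary("huge", 30000, canonical=1))
        fit = ps.fit_length_model(summaries)
        assert fit.n_removed_outliers >= 1

    def test_slope_recovery_with_noise(self):
        rng = np.random.default_rng(7)
        true_slope, true_icpt = 0.003, 0.5
        lengths = rng.integers(100, 2000, size=400)
        log2_counts = true_icpt + true_slope * lengths + rng.normal(0, 1.5, size=400)
        counts = np.maximum(1, np.round(2 ** log2_counts)).astype(int)
        summaries = [
            _summary(f"p{i}", int(l), canonical=int(c))
            for i, (l, c) in enumerate(zip(lengths, counts))
        ]
        fit = ps.fit_length_model(summaries)
        # recovery within a generous CI (rounding to integer counts biases slightly)
        assert abs(fit.slope - true_slope) < 0.001
        assert 0 < fit.r_squared < 1


class TestPositions:
    def test_relative_position_of_center(self):
        m = _match("p", 48)  # center = 50
        hist = ps.positional_distribution([m], {"p": 100}, bin_size=0.02)
        assert hist.counts.sum() == 1
        # relative position 0.50 falls in the bin whose left edge is 0.50
        idx = np.searchsorted(hist.bin_edges, 0.50, side="right") - 1
        assert hist.counts[idx] == 1

    def test_all_mass_in_last_bin(self):
        matches = [_match(f"p{i}", 96) for i in range(5)]
        lengths = {f"p{i}": 98 for i in range(5)}  # center 98 of 98 -> rel 1.0
        hist = ps.positional_distribution(matches, lengths)
        assert hist.counts[-1] == 5 and hist.counts[:-1].sum() == 0

    def test_bin_size_changes_not_total(self):
        rng = np.random.default_rng(5)
        lengths = {f"p{i}": 500 for i in range(50)}
        matches = [_match(f"p{i}", int(rng.integers(1, 496))) for i in range(50)]
        for bs in (0.02, 0.001, 0.1):
            assert ps.positional_distribution(matches, lengths, bin_size=bs).counts.sum() == 50

    def test_exclude_initiator_met_shifts_scale(self):
        m = _match("p", 1)  # center = 3
        h = ps.positional_distribution([m], {"p": 11}, exclude_initiator_met=True)
        # (3-1)/(11-1) = 0.2
        idx = np.nonzero(h.counts)[0][0]
        assert h.bin_edges[idx] <= 0.2 < h.bin_edges[idx + 1] + 1e-12

    def test_uniform_positions_pass_uniformity(self):
        from scipy import stats as sps

        rng = np.random.default_rng(42)
        L = 10000
        centers = rng.integers(3, L - 2, size=4000)
        matches = [_match("p", int(c) - 2) for c in centers]
        hist = ps.positional_distribution(matches, {"p": L}, bin_size=0.02)
        _stat, p = sps.chisquare(hist.counts)
        assert p > 0.01

    def test_terminal_depletion_examples(self):
        L = 40000
        rng = np.random.default_rng(1)
        uniform = [_match("p", int(s)) for s in rng.integers(1, L - 4, size=20000)]
        d = ps.terminal_depletion(uniform, {"p": L})
        assert abs(d) < 12  # ~0 with sampling noise

        tail_only = [_match("p", int(s)) for s in rng.integers(2000, L - 4, size=500)]
        assert ps.terminal_depletion(tail_only, {"p": L}) == pytest.approx(100.0)

    def test_terminal_depletion_half_density_head(self):
        rng = np.random.default_rng(9)
        L = 100000
        f = 0.025
        n = 40000
        p_head = 0.5 * f / (0.5 * f + (1 - f))
        rel = np.where(
            rng.random(n) < p_head,
            rng.uniform(0, f, n),
            rng.uniform(f, 1, n),
        )
        matches = [_match("p", max(1, int(r * L) - 2)) for r in rel]
        d = ps.terminal_depletion(matches, {"p": L})
        assert d == pytest.approx(50.0, abs=5.0)

    def test_terminal_depletion_empty_tail_is_nan(self):
        head = [_match("p", 1)]
        assert math.isnan(ps.terminal_depletion(head, {"p": 1000}))


class TestPositionFrequencies:
    def test_single_motif_rows(self):
        t = ps.aa_position_frequencies([_match("p", 1)], MotifClass.CANONICAL)
        assert t.percentages.loc["K", -4] == 100.0
        assert t.percentages.loc["F", -3] == 100.0
        assert t.percentages.loc["E", -2] == 100.0
        assert t.percentages.loc["R", -1] == 100.0

    def test_mirroring_of_q_left_motifs(self):
        right = ps.aa_position_frequencies([_match("p", 1)], MotifClass.CANONICAL)
        left = ps.aa_position_frequencies(
            [_match("p", 1, penta="QREFK", orient=Orientation.Q_LEFT)],
            MotifClass.CANONICAL,
        )
        pd.testing.assert_frame_equal(right.counts, left.counts)

    def test_rows_sum_to_100(self):
        records, _ = make_proteome(
            n_proteins=50, planted={MotifClass.CANONICAL: 2}, seed=21
        )
        matches = [
            m
            for r in records
            for m in scan_protein(r.sequence, r.accession)
            if m.motif_class is MotifClass.CANONICAL
        ]
        t = ps.aa_position_frequencies(matches, MotifClass.CANONICAL)
        sums = t.percentages.sum(axis=1).dropna()
        assert np.allclose(sums, 100.0)
        assert np.allclose(t.property_percentages.sum(axis=1), 100.0)

    def test_balanced_set_is_uniform(self):
        # K placed once at each of the four variable positions
        matches = [
            _match("p", 1, penta=p)
            for p in ("KFEFQ", "FKFEQ", "FEKFQ", "EFFKQ")
        ]
        t = ps.aa_position_frequencies(matches, MotifClass.CANONICAL)
        assert np.allclose(t.percentages.loc["K"], 25.0)

    def test_wrong_class_raises(self):
        with pytest.raises(ValueError):
            ps.aa_position_frequencies(
                [_match("p", 1, cls=MotifClass.ACETYL, penta="KFERK")],
                MotifClass.CANONICAL,
            )


class TestScrambleAndBaseline:
    def test_scramble_preserves_composition(self, record_factory):
        recs = [record_factory("a", "KFERQDAILV" * 5), record_factory("b", "MMMMKFERQ")]
        scr = ps.scramble_proteome(recs, seed=4)
        for orig, new in zip(recs, scr):
            assert sorted(orig.sequence) == sorted(new.sequence)

    def test_scramble_deterministic(self, record_factory):
        recs = [record_factory("a", "KFERQDAILVWYPCGHMNST" * 3)]
        s1 = ps.scramble_proteome(recs, seed=7)[0].sequence
        s2 = ps.scramble_proteome(recs, seed=7)[0].sequence
        s3 = ps.scramble_proteome(recs, seed=8)[0].sequence
        assert s1 == s2
        assert s1 != s3

    def test_scramble_changes_motif_counts_in_general(self):
        records, _ = make_proteome(n_proteins=30, planted={MotifClass.CANONICAL: 3}, seed=2)
        n_orig = sum(len(scan_protein(r.sequence, r.accession)) for r in records)
        scr = ps.scramble_proteome(records, seed=2)
        n_scr = sum(len(scan_protein(r.sequence, r.accession)) for r in scr)
        assert n_orig != n_scr

    @staticmethod
    def _proteome_like_composition():
        # motif-competent residues common, emulating real-proteome chance
        # motif rates
        comp = {a: 0.08 for a in "KRILVFDEQ"}
        rest = (1 - sum(comp.values())) / 11
        comp.update({a: rest for a in "ACGHMNPSTWY"})
        return comp

    def test_baseline_null_ratios_near_one(self):
        # i.i.d. background sequences: the observed proteome is statistically
        # its own scramble.  Ratios hover around 1 (small-count noise biases
        # them slightly upward) and no strong directional signal appears.
        # The subsample t-test shares the two scanned datasets across
        # replicates, so it is anti-conservative under the global null: a few
        # spurious cells per run are expected, and planted effects must stand
        # far above them -- see the planted test below.
        records, _ = make_proteome(
            n_proteins=300, length_range=(200, 300),
            background_frequencies=self._proteome_like_composition(), seed=10,
        )
        cmp_ = ps.baseline_comparison(records, seed=10)
        assert cmp_.bonferroni_n == 32
        vals = cmp_.ratio_mean.values
        assert np.nanmin(vals) > 0
        assert 0.8 < np.nanmean(vals) < 1.6
        n_sig = int((cmp_.p_corrected.values < 0.05).sum())
        assert n_sig <= 12  # spurious realized-set differences only

    def test_baseline_detects_planted_position_bias(self):
        # plant canonical motifs that always carry E at position -4
        rng = np.random.default_rng(0)
        records, _ = make_proteome(n_proteins=250, length_range=(150, 250), seed=14)
        seqs = []
        for r in records:
            s = list(r.sequence)
            s[10:15] = list("EKFLQ")  # E fixed furthest from the flank
            seqs.append("".join(s))
        biased = [
            type(r)(r.accession, r.entry_name, r.status, r.protein_names,
                    r.gene_name, r.organism, seq)
            for r, seq in zip(records, seqs)
        ]
        cmp_ = ps.baseline_comparison(biased, seed=14)
        assert cmp_.ratio_mean.loc["E", -4] > 1.0
        assert cmp_.p_corrected.loc["E", -4] < 0.05

    def test_identical_inputs_ratio_one(self, record_factory):
        records, _ = make_proteome(n_proteins=120, planted={MotifClass.CANONICAL: 1},
                                   seed=5)
        cmp_ = ps.baseline_comparison(records, seed=5, n_subsamples=10)
        assert cmp_.n_replicates_used <= 10


class TestComposition:
    def test_rows_sum_to_100_and_bias_recovered(self):
        records, _ = make_proteome(
            n_proteins=40,
            planted=[{MotifClass.CANONICAL: 1}, {}],
            exclude_from_background="QKN",
            seed=6,
        )
        summaries = [
            summarize_protein(scan_protein(r.sequence, r.accession), r.accession, r.length)
            for r in records
        ]
        table = ps.composition_comparison(records, summaries)
        assert np.allclose(table.sum(axis=1), 100.0)
        # motif-bearing pool carries the planted Q flanks; the motif-free
        # background has no Q at all
        assert table.loc["with_motif", "Q"] > table.loc["without_motif", "Q"]
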