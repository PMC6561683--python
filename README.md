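# kferqscan

Proteome-wide identification and analysis of **KFERQ-like motifs** — the
pentapeptide targeting signals recognized by the chaperone HSC70 that route
proteins into chaperone-mediated autophagy (CMA) and endosomal
microautophagy (eMI).

The package is aimed at cell biologists and bioinformaticians who want to
(i) find candidate CMA-targeting motifs in single proteins or whole
proteomes, and (ii) run the downstream analyses that put those motifs in
context: abundance and grouping statistics, positional distributions,
solvent-exposure profiles, cross-species conservation scoring, and
functional-annotation enrichment.

## The motif grammar

A KFERQ-like motif is a pentapeptide made of a *flank* residue at the first
or last position and four *variable* residues drawn from three biochemical
categories:

| class | flank | variable region (4 residues) |
|---|---|---|
| canonical | Q | 1–2 basic (K/R), 1–2 hydrophobic (I/L/V/F), exactly 1 acidic (D/E) |
| phosphorylation-generated | Q | 1–2 basic, 1–2 hydrophobic, exactly 1 of S/T/Y (acidic once phosphorylated), no D/E |
| acetylation-generated | K (acidic once acetylated) | as canonical |

Both orientations (flank first or last) are scanned.  In *advanced* mode an
asparagine may stand in for the flanking Q (N-bearing motifs — necessary
but not sufficient for HSC70 binding, so off by default).  Exhaustive
enumeration over all 20⁴ variable regions gives exactly **2,304** oriented
canonical, **3,456** phosphorylation-generated and **2,304**
acetylation-generated windows — a count the test suite recomputes by brute
force.

Downstream statistics include the protein grouping hierarchy (canonical >
phosphorylation- > acetylation-generated > none), fractional motif content
on the ternary simplex, the conservation score

```
score = (n_conserved + 0.5·n_partial − n_noOrtholog) / n_species  ∈ [−1, 1]
```

over CMA-able vs CMA-unable species groups (defined by the LAMP-2A
C-terminal tail signature `[KRH]{3,4}.{1,3}GYEQF$`), and the enrichment
ranking statistic `−ln(p)·z` combining a one-sided Fisher exact p with a
40-replicate annotation-resampling z-score.

## Worked example

Scan a FASTA file (UniProt-style or plain headers) for motifs:

```sh
$ kferqscan --out-dir out scan example.fasta
1 motifs in 2 proteins -> out/finder_report.tsv

$ cat out/finder_report.tsv
entry_name        status   protein_names  gene_name  length  motif_composition  motif_position  motif_type
demo_rnase_nterm  unknown  N-terminal ...            20      KFERQ              7               canonical
```

The scanner found the name-giving pentapeptide `KFERQ` of ribonuclease A —
the founding CMA substrate — starting at residue 7: two basic residues
(K, R), one hydrophobic (F), one acidic (E) and the flanking glutamine.
The negative control contributes no rows.  The same machinery is available
as a library:

```python
>>> from kferqscan import scan_protein, summarize_protein
>>> matches = scan_protein("KETAAAKFERQHMDSSTSAA", "rnase")
>>> [(m.start, m.pentapeptide, m.motif_class.value) for m in matches]
[(7, 'KFERQ', 'canonical')]
```

A protein carrying two canonical, one phosphorylation- and one
acetylation-generated motif has fractional content `(50.0, 25.0, 25.0)` —
the composition used for ternary-plot binning at 5% resolution.

Other subcommands: `stats` (grouping, combinations, length model,
positional distribution), `exposure` (motif-centered ±30-residue
solvent-exposure profile from per-residue RSA tracks, residues with
RSA < 0.25 counted buried), `conserve` (conservation scores from aligned
ortholog families plus a species table), `enrich` (Fisher + resampled-z
term enrichment) and `simulate` (seeded synthetic proteomes with recorded
ground truth).

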