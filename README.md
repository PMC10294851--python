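# mitocompare

Comparative analysis of annotated circular mitochondrial genomes, built
around the mitogenomes of parasitoid wasps (Chalcidoidea: Pteromalidae) but
applicable to any animal mitogenome with the standard 37-gene complement
(13 protein-coding genes, 22 tRNAs, 2 rRNAs) plus an AT-rich control region.

It is aimed at researchers who have annotated mitogenomes — GenBank flat
files or plain gene tables — and want the standard battery of comparative
statistics without stitching together web servers:

* **Composition and strand skew** per region (full genome, PCGs, tRNAs,
  rRNAs, control region): AT skew = (A − T)/(A + T), GC skew = (G − C)/(G + C).
* **Gap/overlap accounting** over all circular gene adjacencies, with the
  convention IGN(next, prev) = start(next) − end(prev) − 1 (touching genes
  score 0; negative values are overlaps).
* **Codon usage**: CDS extraction under the invertebrate mitochondrial code
  (translation table 5) with incomplete-stop (`T-`/`TA-`) classification,
  and relative synonymous codon usage, RSCU(c) = n_c · |family| / Σ family.
* **Ka/Ks** by the Nei–Gojobori (1986) codon-counting method: synonymous and
  nonsynonymous site counts with stop-codon neighbours excluded, difference
  counts averaged over all mutational pathways (stop-crossing pathways
  excluded), Jukes–Cantor correction d = −(3/4)·ln(1 − (4/3)·p).
* **Gene-order rearrangement**: signed circular gene orders, pairwise
  breakpoint distances on unsigned circular adjacencies, conserved gene
  blocks, and greedy classification of inversions, transpositions, reverse
  transpositions and TDRL-or-complex residues, with exact replay.
* **Trees**: neighbor joining from breakpoint matrices, and Fitch parsimony
  reconstruction of ancestral parasitic lifestyle (1 = primary parasitoid,
  2 = primary + hyperparasitoid, 3 = undefined, treated as ambiguity).
* **Synthetic data**: a seeded generator of annotated circular mitogenomes
  (configurable AT bias, valid codon structure, planted rearrangements and
  planted synonymous/nonsynonymous changes) for controlled testing.

Gene tables for the four newly sequenced pteromalid mitogenomes
(GenBank MT712139–MT712142: *Muscidifurax similadanacus*, *M. sinesensilla*,
*Nasonia vitripennis*, *Pachycrepoideus vindemmiae*) ship as fixtures.

## Worked example

```python
from mitocompare.datasets import load_all_records
from mitocompare import (order_from_record, pbd_matrix, adjacency_report,
                         pcg_summary, classify_events)

records = load_all_records()
orders = [order_from_record(r) for r in records.values()]
print(pbd_matrix(orders).values)
```

prints the pairwise breakpoint-distance matrix

```
                  M. similadanacus  M. sinesensilla  N. vitripennis  P. vindemmiae
M. similadanacus                 0                0               0              5
M. sinesensilla                  0                0               0              5
N. vitripennis                   0                0               0              5
P. vindemmiae                    5                5               5              0
```

i.e. the two *Muscidifurax* species and *N. vitripennis* share one
arrangement (distance 0), while *P. vindemmiae* differs from each by five
broken adjacencies. Classifying the events behind those five breakpoints:

```python
src = order_from_record(records["M_similadanacus"])
tgt = order_from_record(records["P_vindemmiae"])
for e in classify_events(src, tgt):
    print(e.kind, "-".join(e.segment))
# reverse_transposition trnR
# inversion trnN
# inversion trnE-trnF
```

the *trnR* relocation (with strand flip), a strand flip of *trnN*, and the
*trnE*–*trnF* inversion. Gap/overlap accounting and the protein-coding share
for *P. vindemmiae*:

```python
rep = adjacency_report(records["P_vindemmiae"])
print(rep.gap_total, rep.overlap_total, rep.longest_gap)
# 97 23 ('trnI', 'nad2', 35)      # 97 bp of gaps, 23 bp of overlaps,
                                  # longest gap 35 bp between trnI and nad2
print(pcg_summary(records["P_vindemmiae"]))
# (11092, 74.69)                  # PCGs span 11092 bp = 74.69% of the genome
```

The same operations are exposed on the command line (`mitocompare stats`,
`gaps`, `rscu`, `kaks`, `bpdist`, `blocks`, `events`, `njtree`, `fitch`,
`simulate`, `convert`); `mitocompare --help` lists them.

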