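# staligner

A desk-scale short-read alignment toolkit built around four pieces:

* **FM-index core** (`staligner.fm_index`) — suffix array (prefix doubling),
  BWT, C array, bucketed Occ checkpoints, sampled suffix array; backward
  search, counting and locate queries.
* **Suffix Tarray** (`staligner.suffix_tarray`) — a frequency-truncated trie
  over the reversed reference whose nodes cache SA intervals, so backward
  search descends the trie without Occ work and falls back to plain FM
  extension below it. The frequency threshold is auto-selected by binary
  search as the smallest value whose trie fits a byte budget (36 bytes per
  node). Results are identical to FM-only search by construction; only the
  speed changes.
* **Lower-bound pruning** (`staligner.pruning`) — two per-prefix lower
  bounds on the edit cost of a read against the reference ("D-arrays"):
  the single-mismatch window-break segmentation, and a tighter bound that
  additionally consumes frequent substrings mined from training reads and
  known to need exactly two edits, organized in an Aho–Corasick automaton
  with reset-on-match scanning. Both bounds charge gap extensions 1.
* **Inexact search** (`staligner.aligner`) — BWA-style bounded backtracking
  over the read from its end, branching on match / substitution / deletion /
  insertion, with gap opens costing 1 and up to a capped number of
  consecutive deletion extensions costing 0, pruned wherever the remaining
  budget drops below the D-array bound. Because the search metric charges
  extensions 0 while the D-arrays charge them 1, the tighter bound can
  prune a within-budget gapped alignment that the basic bound keeps; this
  documented divergence is reproduced by a regression test.

Plus `staligner.simeval` (wgsim-style read simulation with truth-encoding
names, TPR/PPV/confident-rate scoring) and `staligner.io` / `staligner.cli`
(FASTA/FASTQ parsing, SAM output, a versioned JSON index container, and the
command line).

## CLI

```bash
staligner index ref.fa -o ref.idx --trie-size 1000000     # build index
staligner train ref.idx training.fq -o auto.json          # mine 2-edit patterns
staligner aln ref.idx reads.fq -o out.sam -n 5 -e 3 -l 25 \
    --use-dcdc --automaton auto.json                      # align (SAM out)
staligner simulate ref.fa -o reads.fq --truth truth.tsv -n 2000 -e 0.02
staligner evaluate out.sam truth.tsv                      # TPR/PPV report
```

`aln` flags mirror the usual conventions: `-n` maximum differences, `-e`
maximum free gap extensions, `-l` seed length (0 disables seeding),
`--disable-sta` drives the search with raw FM intervals, and `-t` is
accepted and ignored (single-threaded).

Mapping quality is a simplified documented scheme: 37 for a unique best
placement with an empty runner-up stratum, 0 for ambiguous placements, and
a decreasing function of the number of competing loci otherwise (always in
[0, 60]); the evaluator calls a read confident at quality >= 10.

## Notes

* All indices are 0-based internally (row 0 of the suffix array is the
  sentinel suffix); SAM output is 1-based.
* `N` bases in references are replaced by a deterministic pseudo-random
  base from a fixed seed; `N` in reads never matches anything and is
  resolved by the substitution branch.
* Multi-record references are concatenated with separator characters, so
  no alignment can span two records.
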