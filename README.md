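# wolclock

Analysis toolkit for dating the divergence of maternally inherited
endosymbionts and for characterizing selection on their incompatibility
loci.  The package implements:

- **divergence** — in-frame codon alignments, Jukes-Cantor-corrected
  third-position divergence, NG86 synonymous-site divergence, and
  endosymbiont/nuclear/mtDNA divergence-ratio tables.
- **calibration** — substitution-rate estimates from cladogenic
  host/symbiont co-divergence (`rate = (d/100) / (2T)`), credible-interval
  propagation from host divergence times, equal-weight pooling, and the
  named rate priors `N1`, `U1`, `N2`, `U2` and `legacy` as seeded samplers.
- **chronoscale** — converting relative-chronogram posterior samples (root
  age 1, plus per-sample third-position rate multipliers) into absolute
  chronograms with medians and 95% credible intervals, and collapsing
  weakly supported nodes (posterior < 0.95) into polytomies.
- **treedist** — Robinson-Foulds, Jaccard-RF (optimal split matching) and
  clustering-information distances, normalized by the mean distance of
  random tree pairs, with permutation p-values for topological similarity.
- **structdnds** — spherical sliding-window dN/dS (default 10 Å) mapped
  onto protein structures (CA coordinates from PDB files), NA-aware median
  profiles across pairwise comparisons, BCa bootstrap intervals,
  Mann-Whitney / Kruskal-Wallis + Dunn group comparisons with compact
  letter displays, Kabsch superposition with TM-scores, and Spearman
  correlation.
- **ci_assay** — egg-hatch tables, low-egg-count filtering (< 10 eggs),
  pooled 5-day hatch proportions, one-sided rank-sum tests of IC < CC.
- **synthetic_data** — seeded simulators (birth-death trees, GTR+Γ
  alignments with codon-position multipliers and Γ(7,7) relaxed branch
  rates, codon alignments with regional dN/dS, ideal helices, hatch
  tables, fake chronogram posteriors) so the full pipeline runs offline.

Small published calibration tables (divergences, host divergence times,
ratio cells) ship as TSV fixtures in `wolclock.data` and are exposed via
`wolclock.datasets`.

## Command line

The `wolclock` entry point groups the analyses:

```sh
wolclock divergence --aln genes.fasta --kind third --pairs spA,spB
wolclock calibrate  --pairs pairs.tsv --out rates.tsv
wolclock prior      --name N1 --n 100000 --seed 1 --out draws.tsv
wolclock scale      --trees post.nwk --m3 rates.tsv --prior N1 --draws 100 --seed 7
wolclock treedist   --t1 a.nwk --t2 b.nwk --metric CID --n-random 10000 --seed 11
wolclock sphere-dnds --aln cif.fasta --ref refTaxon --structure ref.pdb --radius 10
wolclock ci-test    --table hatch.tsv --min-eggs 10
wolclock simulate tree|alignment|hatch|posterior ...
```

`pairs.tsv` columns: `name, d_third_percent, d_syn_percent, T_years, T_low,
T_high` (tab-separated, `NA` allowed for missing bounds).  Posterior input
is a newick list plus a TSV with an `m3` column, one row per tree.

## Notes

- Rates are carried in substitutions/site/year everywhere; `×10⁻⁹`
  formatting is presentation-only.
- Priors are sampled literally (normal components can produce rare
  non-positive draws); pass `positive_only=True` (used automatically when
  scaling chronograms) to reject them.
- Credible intervals are equal-tailed percentiles; the chronogram point
  estimate is the posterior median.
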