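# specprofiler

Quantitative analyses behind the design and validation of protein
inhibitors that each target one of the six human pro-survival BCL2-family
proteins (Bcl-2, Bcl-xL, Bcl-w, Mcl-1, Bfl-1, Bcl-B). Such inhibitors are
three-helix bundles presenting a BH3-mimetic helix; making each one bind
its own homolog hundreds-fold more tightly than the other five requires
three kinds of quantitative evidence, and this package implements all
three as a tested pipeline:

1. **SSM enrichment landscapes** (`specprofiler.ssm`) — a site-saturation
   mutagenesis library (every single amino-acid substitution) is displayed
   on yeast and FACS-sorted for specific binding; deep sequencing of the
   naive and sorted pools gives each variant an enrichment ratio

   `e(i,a) = log2[ ((c_sorted + p)/(N_sorted + pV)) / ((c_naive + p)/(N_naive + pV)) ]`

   with pseudocount `p = 0.5`, pool totals `N`, and `V` matrix cells.
   On top of the (position x 21) matrix the module masks low-coverage
   cells, centers each position on its 20-amino-acid mean, measures how
   far each designed residue sits from the per-position optimum
   (deviation from maximum / from mean), selects specificity mutations
   (enriched on-target, depleted against every competitor sort), and
   flags destabilizing proline/stop enrichment.

2. **Binding kinetics and specificity** (`specprofiler.bli`) —
   biolayer-interferometry titrations are fit globally (kon, koff, Rmax
   shared across concentrations) to the 1:1 Langmuir model

   `R(t) = Rmax * C/(C + KD) * (1 - exp(-(kon*C + koff) t))`,  `KD = koff/kon`,

   with dissociation `R0 exp(-koff t)`. Pairs with no sustained signal
   are censored (`KD > top tested concentration`), and fold-specificity
   is `min over off-targets of KD_off / KD_on`, reported as a lower bound
   when the limiting off-target is censored. CD denaturation scans are
   normalized to fraction folded.

3. **Structural validation** (`specprofiler.structure`) — Kabsch
   superposition and target-aligned partner RMSD (align the shared target
   chain, measure the inhibitor chain without refitting, averaged over
   NCS copies); Shrake–Rupley SASA (probe 1.4 Å, 960 points/atom) and
   two-sided buried surface area `SASA(A) + SASA(B) - SASA(AB)` with
   interface-expansion differences; Cα mapping of lysine cross-links
   (DSS/BS3 limit 30 Å, DSG 26 Å) with reagent-support summaries; and
   docking-funnel statistics (mean ddG of the 100 lowest-scoring local
   and global docking records, absolute = local minimum, relative =
   local − global).

`specprofiler.profiles` adds alignment conservation scored by counting
distinct physicochemical amino-acid categories per column, consensus
shading (identical/similar/different), and BH3 hotspot register h0–h4
bookkeeping including uniform register shifts (+4 = one helical turn).
`specprofiler.synth` generates every input class with a ground-truth
ledger, so the full pipeline runs and is tested without downloads.

## Worked example

`analysis/` holds the numbered drivers; each writes tables to `results/`.
Fitting the six-inhibitor titration panel:

```bash
python analysis/02_binding_kinetics.py
```

```
aBCL2: on-target Bcl-2 KD 0.202 nM (true 0.200 nM), specificity 490-fold vs Mcl-1
aBCLB: on-target Bcl-B KD 1.489 nM (true 1.500 nM), specificity 354-fold vs Bcl-2
aBCLW: on-target Bcl-w KD 0.988 nM (true 1.000 nM), specificity 400-fold vs Bcl-xL
aBCLXL: on-target Bcl-xL KD 0.502 nM (true 0.500 nM), specificity 791-fold vs Bcl-w
aBFL1: on-target Bfl-1 KD 0.495 nM (true 0.500 nM), specificity 602-fold vs Mcl-1
aMCL1: on-target Mcl-1 KD 0.049 nM (true 0.050 nM), specificity 1993-fold vs Bfl-1
```

Each line is one inhibitor: the globally refit on-target dissociation
constant (against the value the generator planted) and the smallest
off-target/on-target KD ratio with the homolog that limits it — every
inhibitor in the panel clears 300-fold specificity. The other drivers
cover the SSM landscape (`01`), structural validation (`03`), docking
funnels (`04`) and conservation/register analysis (`05`).

## External data layout (optional)

To run the two experiment-backed tests, place under `data/external/`:

- `ssm_enrichment/<design>.tsv` — per-design enrichment matrices
  (positions as rows, 21 amino-acid columns, `NA` for missing) with
  `<design>.designed.txt` holding the designed sequence;
- `bli_traces.csv` — titration traces, long format
  (`inhibitor,homolog,phase,conc_M,time_s,signal`);
- `5JSN.pdb`, `5JSB.pdb`, `3KZ0.pdb`, `2XA0.pdb` — deposited crystal
  structures of the inhibitor–target and reference BH3 complexes;
- `crosslinks_5JSB.tsv` — identified cross-links
  (`chain_a,res_a,chain_b,res_b,reagents`).
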