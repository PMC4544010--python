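# 2000-cell reporter-infidelity fixture pairing Nanog mRNA counts with
# Nanog:VNP reporter counts (cutoff 30 for both).  The class mix (15%
# Nanog(-)) and fn_fraction = 0.15/0.85 imply that exactly half of the
# reporter-negative cells are truly Nanog-positive in expectation; reporter
# false negatives keep the Nanog(+) mRNA count distribution.
fn_fraction: 0.17647058823529413
n_cells: 2000
mrna_gene: Nanog
reporter_gene: VNP
mrna_cutoff: 30
reporter_cutoff: 30
fn_reporter_dist: {family: negative-binomial, loc: 5, shape: 0.3, guard: {cutoff: 30, side: "-"}}
base_classes:
  seed: 20150824
  genes: [Nanog, VNP]
  guard_margin: 0.2
  classes:
    - name: NanogPos
      n_cells: 1700
      genes:
        Nanog: {family: lognormal-rounded, loc: 300, shape: 0.45, guard: {cutoff: 30, side: "+"}}
        VNP:   {family: lognormal-rounded, loc: 150, shape: 0.45, guard: {cutoff: 30, side: "+"}}
    - name: NanogNeg
      n_cells: 300
      genes:
        Nanog: {family: negative-binomial, loc: 5, shape: 0.5, guard: {cutoff: 30, side: "-"}}
        VNP:   {family: negative-binomial, loc: 5, shape: 0.5, guard: {cutoff: 30, side: "-"}}
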