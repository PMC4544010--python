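# 1189-cell Nanog/Oct4 fixture.  Composition: 1129 Nanog(+)Oct4(+),
# 16 Nanog(-)Oct4(+), 44 Nanog(-)Oct4(-); cutoffs 30 (Nanog) and 80 (Oct4).
# Guarded distributions: classification recovers the latent classes exactly.
seed: 20150821
genes: [Nanog, Oct4]
guard_margin: 0.2
classes:
  - name: NanogPosOct4Pos
    n_cells: 1129
    genes:
      Nanog: {family: lognormal-rounded, loc: 300, shape: 0.45, guard: {cutoff: 30, side: "+"}}
      Oct4:  {family: lognormal-rounded, loc: 360, shape: 0.40, guard: {cutoff: 80, side: "+"}}
  - name: NanogNegOct4Pos
    n_cells: 16
    genes:
      Nanog: {family: negative-binomial, loc: 5, shape: 0.5, guard: {cutoff: 30, side: "-"}}
      Oct4:  {family: lognormal-rounded, loc: 200, shape: 0.40, guard: {cutoff: 80, side: "+"}}
  - name: NanogNegOct4Neg
    n_cells: 44
    genes:
      Nanog: {family: negative-binomial, loc: 5, shape: 0.5, guard: {cutoff: 30, side: "-"}}
      Oct4:  {family: negative-binomial, loc: 20, shape: 0.3, guard: {cutoff: 80, side: "-"}}
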