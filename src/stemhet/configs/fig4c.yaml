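# 764-cell Tbx6/T/Oct4 fixture.  Two Tbx6(+) cells, both inside the seven
# T(+) cells, all T(+) cells Oct4(-).  Cutoffs: Tbx6 10, T 50, Oct4 80.
seed: 20150823
genes: [Tbx6, T, Oct4]
guard_margin: 0.2
classes:
  - name: Oct4Pos
    n_cells: 745
    genes:
      Tbx6: {family: negative-binomial, loc: 1, shape: 0.5, guard: {cutoff: 10, side: "-"}}
      T:    {family: negative-binomial, loc: 2, shape: 0.5, guard: {cutoff: 50, side: "-"}}
      Oct4: {family: lognormal-rounded, loc: 360, shape: 0.40, guard: {cutoff: 80, side: "+"}}
  - name: Oct4NegNoMarker
    n_cells: 12
    genes:
      Tbx6: {family: negative-binomial, loc: 1, shape: 0.5, guard: {cutoff: 10, side: "-"}}
      T:    {family: negative-binomial, loc: 2, shape: 0.5, guard: {cutoff: 50, side: "-"}}
      Oct4: {family: negative-binomial, loc: 20, shape: 0.3, guard: {cutoff: 80, side: "-"}}
  - name: TPosOct4Neg
    n_cells: 5
    genes:
      Tbx6: {family: negative-binomial, loc: 1, shape: 0.5, guard: {cutoff: 10, side: "-"}}
      T:    {family: lognormal-rounded, loc: 200, shape: 0.50, guard: {cutoff: 50, side: "+"}}
      Oct4: {family: negative-binomial, loc: 20, shape: 0.3, guard: {cutoff: 80, side: "-"}}
  - name: Tbx6PosTPosOct4Neg
    n_cells: 2
    genes:
      Tbx6: {family: lognormal-rounded, loc: 40, shape: 0.40, guard: {cutoff: 10, side: "+"}}
      T:    {family: lognormal-rounded, loc: 200, shape: 0.50, guard: {cutoff: 50, side: "+"}}
      Oct4: {family: negative-binomial, loc: 20, shape: 0.3, guard: {cutoff: 80, side: "-"}}
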