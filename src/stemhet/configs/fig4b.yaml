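# 2360-cell Nanog/Crabp2/T fixture.  138 Nanog(-) cells of which 25 express a
# lineage marker; exactly 2 cells are Crabp2(+)T(+).  Cutoffs: Nanog 30,
# Crabp2 30, T 50.  Marker-positive levels: tens (Crabp2) / hundreds (T) of
# transcripts.
seed: 20150822
genes: [Nanog, Crabp2, T]
guard_margin: 0.2
classes:
  - name: NanogPos
    n_cells: 2222
    genes:
      Nanog:  {family: lognormal-rounded, loc: 300, shape: 0.45, guard: {cutoff: 30, side: "+"}}
      Crabp2: {family: negative-binomial, loc: 2, shape: 0.5, guard: {cutoff: 30, side: "-"}}
      T:      {family: negative-binomial, loc: 2, shape: 0.5, guard: {cutoff: 50, side: "-"}}
  - name: NanogNegNoMarker
    n_cells: 113
    genes:
      Nanog:  {family: negative-binomial, loc: 5, shape: 0.5, guard: {cutoff: 30, side: "-"}}
      Crabp2: {family: negative-binomial, loc: 2, shape: 0.5, guard: {cutoff: 30, side: "-"}}
      T:      {family: negative-binomial, loc: 2, shape: 0.5, guard: {cutoff: 50, side: "-"}}
  - name: NanogNegCrabp2Pos
    n_cells: 15
    genes:
      Nanog:  {family: negative-binomial, loc: 5, shape: 0.5, guard: {cutoff: 30, side: "-"}}
      Crabp2: {family: lognormal-rounded, loc: 60, shape: 0.40, guard: {cutoff: 30, side: "+"}}
      T:      {family: negative-binomial, loc: 2, shape: 0.5, guard: {cutoff: 50, side: "-"}}
  - name: NanogNegTPos
    n_cells: 8
    genes:
      Nanog:  {family: negative-binomial, loc: 5, shape: 0.5, guard: {cutoff: 30, side: "-"}}
      Crabp2: {family: negative-binomial, loc: 2, shape: 0.5, guard: {cutoff: 30, side: "-"}}
      T:      {family: lognormal-rounded, loc: 200, shape: 0.50, guard: {cutoff: 50, side: "+"}}
  - name: NanogNegDoublePos
    n_cells: 2
    genes:
      Nanog:  {family: negative-binomial, loc: 5, shape: 0.5, guard: {cutoff: 30, side: "-"}}
      Crabp2: {family: lognormal-rounded, loc: 60, shape: 0.40, guard: {cutoff: 30, side: "+"}}
      T:      {family: lognormal-rounded, loc: 200, shape: 0.50, guard: {cutoff: 50, side: "+"}}
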