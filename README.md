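# tesseloc

Tessellation-based colocalization analysis for 2D and 3D multicolor
single-molecule localization microscopy (SMLM).

Multicolor SMLM produces one list of molecular coordinates per channel
rather than pixel images, so the classical intensity-based
colocalization estimators do not apply directly, and most
coordinate-based alternatives require a user-chosen interaction
distance that strongly influences the result.  `tesseloc` quantifies
the co-organization of two localization channels without any such
parameter by overlaying their Voronoï diagrams.  It is aimed at
microscopists analyzing two-color dSTORM / PALM / DNA-PAINT data and at
method developers who need a reproducible, scriptable reference
implementation with a built-in simulation suite.

## Method

For each channel the Voronoï diagram assigns every localization
*s<sub>i</sub>* a polytope *P<sub>i</sub>* (polygon in 2D, polyhedron in
3D).  Its first-rank density pools the cell with its facet-sharing
neighbors,

δ<sub>i</sub> = (n<sub>i</sub> + 1) / (A<sub>i</sub> + Σ<sub>j∈N(i)</sub> A<sub>j</sub>),

and is normalized by the average density δ of a spatially random
reference over the field, δ̂<sub>i</sub> = δ<sub>i</sub>/δ, which makes
the descriptor independent of the absolute molecular density.  Each
localization of channel A is then paired with the channel-B cell it
falls into, giving scatterplot coordinates
(x<sub>i</sub><sup>A</sup>, y<sub>i</sub><sup>A</sup>) =
(δ̂<sub>i</sub><sup>A</sup>, δ̂<sub>j</sub><sup>B</sup>), and symmetrically
for B.  A single threshold *T* (default 1, i.e. "denser than random")
splits each channel into a high-density class and background, and the
partner density subdivides the high classes into five classes:
colocalized (C<sup>AB</sup>, C<sup>BA</sup>), high in one channel only
(C<sup>AB̄</sup>, C<sup>BĀ</sup>), and background.  Because Voronoï
cells on the rim of dense structures are systematically oversized, an
edge correction re-tests every C<sup>AB</sup>/C<sup>BA</sup>
localization against the Delaunay triangle set of the other channel's
high class, after discarding triangles larger than q75 + 1.5·IQR of the
triangle-measure distribution.

Two coefficients summarize each channel:

- **Manders** — the density-weighted fraction of the high class that
  remains colocalized after correction:
  M<sup>A</sup> = Σ α<sub>i</sub> x<sub>i</sub><sup>A</sup> / Σ x<sub>i</sub><sup>A</sup>
  over s<sub>i</sub><sup>A</sup> ∈ C<sup>A</sup>, with α<sub>i</sub> = 1
  iff s<sub>i</sub><sup>A</sup> ∈ corr(C<sup>AB</sup>).
- **Spearman** — the rank correlation between own and partner
  normalized densities over all localizations of the channel
  (average ranks for ties).

The package also implements the standard preprocessing around the
analysis (translation and third-order polynomial chromatic
registration from fiducial markers, neighbor-count bead filtering), a
two-level Voronoï cluster segmentation with inter-channel barycenter
distances, and the two-color cluster simulator used for validation.

## Worked example

Simulate the partially colocalized reference condition (100 nm circular
and square clusters whose centers are 50 nm apart) and analyze it:

```
$ tesseloc simulate --seed 7 --distance 50 --out demo
$ tesseloc coloc --a demo.A.csv --b demo.B.csv --seed 7 --out run
INFO n_A=20354 n_B=23543 counts={'AB': 4517, 'Ab': 8118, 'BA': 4553, 'Ba': 10876, 'bg': 15833} beads_removed=0 elapsed=3.88s
summary written to run.summary.json
$ cat run.summary.json
{
  "M_A": 0.36831913156883456,
  "M_B": 0.297285407255681,
  "S_A": 0.44290288134420636,
  "S_B": 0.35645696387563947,
  ...
}
```

Reading the output: about 37% of channel A's density-weighted
high-density signal sits inside high-density regions of channel B
(M_A), and the pair densities are moderately rank-correlated
(S_A ≈ 0.44) — the signature of partial overlap.  A fully colocalized
simulation (`--distance 0`) gives M_A ≈ 0.95 and S_A ≈ 0.73; fully
separated clusters (`--distance 125`) give M_A ≈ 0.00 and a negative
S_A.  The per-localization table `run.locs.csv` carries the class label
and the (δ̂ own, δ̂ partner) pair for every localization, so results can
be re-rendered or re-thresholded downstream.

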