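# gefprobe

Analysis toolkit for asking whether a candidate guanine-nucleotide exchange
factor (GEF) domain is plausibly functional, combining in vitro exchange
kinetics with structure- and sequence-based evidence.

## The scientific problem

Rho-family GTPases are molecular switches activated by GEFs, which catalyse
the release of bound GDP. Many proteins carry domains annotated as Rho GEFs
(DH/PH tandems) purely by homology, yet annotation does not guarantee
catalytic activity. Deciding whether such a domain is a working exchange
factor requires several independent lines of evidence:

1. **Exchange kinetics.** In a fluorescence exchange assay (e.g. mant-GDP
   release), the signal decays as nucleotide is exchanged. Each trace is fit
   with the mono-exponential model

   `f(t) = (a0 − a_plateau) · exp(−k_obs · t) + a_plateau`

   after normalising to the mean of a pre-reaction baseline window. A GEF is
   called *active* when the fold change `k_obs(GEF) / k_obs(intrinsic)`
   exceeds a threshold **and** its bootstrap confidence interval excludes 1.
   A flat trace (no detectable decay) is itself a meaningful result for an
   inactive enzyme and is detected and flagged rather than force-fit.

2. **Steric binding compatibility.** Conformational ensembles of the GEF
   domain (e.g. from MD or NMR) are superposed residue-by-residue onto a
   crystallographic GEF:GTPase complex used as a template. Frames in which a
   flexible region intrudes into the space occupied by the GTPase — atom
   pairs with van der Waals overlap `(r_i + r_j) − d ≥ 0.4 Å` — are
   incompatible with binding; the pipeline reports the percentage of
   compatible frames.

3. **Ensemble statistics.** Per-frame RMSD, per-residue RMSF, and
   Cartesian-coordinate PCA (covariance of superposed Cα coordinates,
   strided subsampling, eigenvalue spectra, per-frame projections, and
   extreme-projection structures) characterise and compare the flexibility
   of ensembles, e.g. across species orthologs.

4. **Sequence evidence.** Pairwise percent-identity matrices over a multiple
   sequence alignment, greedy diagonal-square clustering of the identity
   matrix (the square-neighbourhood criterion used for DH-domain family
   maps), divergence of catalytically key residues relative to conserved
   columns, and affine-gap global alignment (BLOSUM62) for cross-species
   identity checks.

All four strands, plus ground-truth synthetic data generators for each of
them, are tied together by a configuration-driven pipeline with a
deterministic, byte-reproducible report.

## Worked example

Fit exchange kinetics for three GEF-arm and three intrinsic-arm replicates
(synthetic traces with 1 h records, 5 s sampling, 300 s baseline), then
classify activation:

```python
from gefprobe import synth
from gefprobe.kinetics import classify_activation, fit_monoexponential, normalize_trace

gef, intrinsic = [], []
for cond, k, seeds in [("gef", 8e-3, (11, 12, 13)), ("intrinsic", 1.1e-3, (21, 22, 23))]:
    for s in seeds:
        trace, _ = synth.make_trace(1.0, 0.4, k, 0.01, duration_s=3600,
                                    sampling_s=5.0, seed=s)
        fit = fit_monoexponential(normalize_trace(trace))
        (gef if cond == "gef" else intrinsic).append(fit)
        print(f"{cond}: k_obs = {fit.k_obs:.3e} /s  (SE {fit.se_k_obs:.1e})")

call = classify_activation(gef, intrinsic, seed=0)
print(f"fold activation = {call.fold_activation:.2f}, 95% CI = "
      f"({call.ci_95[0]:.2f}, {call.ci_95[1]:.2f}), call = {call.call}")
```

Output:

```
gef: k_obs = 7.972e-03 /s  (SE 7.6e-05)
gef: k_obs = 7.993e-03 /s  (SE 7.7e-05)
gef: k_obs = 7.963e-03 /s  (SE 7.8e-05)
intrinsic: k_obs = 1.106e-03 /s  (SE 6.8e-06)
intrinsic: k_obs = 1.096e-03 /s  (SE 7.0e-06)
intrinsic: k_obs = 1.094e-03 /s  (SE 7.1e-06)
fold activation = 7.26, 95% CI = (7.21, 7.30), call = active
```

Steric compatibility and PCA on synthetic ensembles with known truth:

```python
from gefprobe.clash import compatibility_fraction
from gefprobe.pca import fit_pca

ens, tpl, rmap, rm, rt, truth = synth.make_binding_scenario(0.3, 50, seed=42)
res = compatibility_fraction(ens, tpl, rmap, rm, rt)
print(f"compatible frames: {res.n_compatible}/{res.n_frames} "
      f"({res.percent_compatible:.1f}%); ground truth intrusions: {truth['n_intruded']}")

modes, _ = synth.make_mode_ensemble(30, [4.0, 1.0], 500, seed=7)
m = fit_pca(modes, stride=5, n_components=10)
print(f"PCA on {m.n_frames_used} frames (stride {m.stride_used}): "
      f"variance fractions {[round(float(v), 3) for v in m.variance_fraction[:3]]}")
```

Output:

```
compatible frames: 38/50 (76.0%); ground truth intrusions: 12
PCA on 100 frames (stride 5): variance fractions [0.734, 0.266, 0.0]
```

## Command line

Every operation is also exposed through the `gefprobe` CLI:

```bash
gefprobe run --config config.yaml        # full configurable pipeline
gefprobe synth binding --seed 3 --out scenario/   # write a ground-truth scenario
gefprobe clash --ensemble frames.pdb --template complex.pdb \
    --anchor-mobile A:1-50 --anchor-template A:1-50 \
    --region-mobile A:62-78 --region-template B:120-133 --out clashes.csv
gefprobe rmsf / pca / identity / clusters / divergence / align
gefprobe kinetics fit / kinetics classify
```

`gefprobe run` consumes a YAML config enabling any subset of the stages
`ensemble`, `pca`, `clash`, `msa`, `kinetics` on user files or bundled
synthetic scenarios, and writes CSV artifacts plus a `report.json` that is
byte-identical across reruns of the same config.

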