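# mirpls

Nonlinear partial least squares with a **monotone cubic spline inner model**
and an invertibility-based weight-updating strategy, for calibration problems
with strongly collinear predictors and monotone nonlinear responses
(dose–effect panels, NIR spectra and the like).

Each latent component relates the input scores `t = X w` to the output scores
`u` through a C² piecewise-cubic spline constrained to be monotone, with
interior knots placed at empirical quantiles of the scores. Because the inner
model is monotone it is invertible; the discrepancy `e = φ⁻¹(u) − t` is
regressed on the current predictor residual with a nested two-component
linear PLS, and the resulting coefficient vector corrects the input weights.
Components are extracted sequentially with bilinear deflation, exactly as in
standard NIPALS.

The package also provides:

* `linear_pls` — a NIPALS linear PLS baseline (also the nested regression
  inside the weight update),
* `monotone_spline` — constrained least-squares fitting, evaluation and
  inversion of the monotone inner model,
* `evaluation` — RMSE / MAPE / R² metrics, LOO and k-fold cross-validated
  grid search over (components, knots), the k % improvement statistic and an
  exact Wilcoxon signed-rank comparison of paired prediction errors,
* `synthetic_data` — deterministic generators for collinear predictors with
  monotone nonlinear latent responses (dose-effect-shaped and spectra-shaped
  fixtures with known ground truth),
* `cli_io` — CSV readers/writers, versioned JSON model files and the CLI.

## CLI

```bash
# simulate a collinear nonlinear dataset with known truth
mirpls simulate --spec spec.json --out-x X.csv --out-y y.csv --out-truth truth.json

# fit / predict
mirpls fit --x X.csv --y y.csv --lv 2 --knots 1 --out model.json
mirpls predict --model model.json --x Xnew.csv --out yhat.csv

# cross-validated grid search (components 1-15, knots 0-5 by default)
mirpls cv --x X.csv --y y.csv --lv-grid 1:15 --knot-grid 0:5 \
          --scheme kfold --k 5 --seed 7 --report cv.json

# metrics and paired model comparison
mirpls metrics --y y.csv --yhat yhat.csv
mirpls compare --errors-a a.csv --errors-b b.csv
```

Files are plain CSV with a header row (rows = samples, columns = variables),
written with round-trip-stable floats. `mirpls fit --plot-inner out.png`
dumps a t-vs-u scatter with the fitted inner curve for the first component.
Errors exit nonzero with a one-line `error:<category>: message` report.

## Notes on numerics

* Spline fitting solves the inequality-constrained least-squares problem
  (derivative ≥ 0 on a dense grid) exactly, via the Lawson–Hanson
  LSI → LDP → NNLS transformation inside an outer active-set loop; analytic
  per-piece minima of the derivative are added as cutting planes so the fit
  is monotone everywhere at the 1e-9 level, not just on the grid.
* Inversion uses bracketed bisection on the evaluator; flat stretches map to
  the midpoint of the preimage interval, and queries outside the fitted range
  invert the linear boundary extrapolation.
* Autoscaling uses the sample standard deviation (N−1); constant columns are
  centered, flagged and given divisor 1.
* R² is never clamped: negative values are reported as-is.
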