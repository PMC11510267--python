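"""Calibration-curve quantification of one constituent.

Builds a six-level calibration series for gallic acid, fits the line,
converts triplicate peak areas back to contents in mg per g of lyophilized
extract powder, and prints the mean +/- SD.
"""

from dbaffinity import ExtractionFactors, fit_calibration, quantify, \
    replicate_stats, simulate_calibration

TRUE_SLOPE, TRUE_INTERCEPT = 850.0, 12.0  # area per (ug/mL), area
TRUE_CONTENT = 4.800  # mg/g powder

pts = simulate_calibration(TRUE_SLOPE, TRUE_INTERCEPT, noise_rel=0.01, seed=5)
curve = fit_calibration(pts, standard_id=29)
print(f"calibration: area = {curve.slope:.1f} x conc + {curve.intercept:.1f}, "
      f"r = {curve.r:.5f} ({curve.n_points} levels)")

factors = ExtractionFactors()  # 30 mg powder/mL; 0.3 g powder per 10 g leaves
conc = TRUE_CONTENT * factors.solution_conc  # ug/mL in the injected solution
import numpy as np
rng = np.random.default_rng(6)
areas = (TRUE_SLOPE * conc + TRUE_INTERCEPT) * (1 + rng.normal(0, 0.01, 3))
contents = [quantify(a, curve, factors, basis="powder") for a in areas]
est = replicate_stats(contents, standard_id=29)
print(f"recovered content: {est.mean:.3f} +/- {est.sd:.3f} mg/g "
      f"(n = {est.n}; truth {TRUE_CONTENT:.3f})")
print("The content is mg of constituent per g of lyophilized extract powder;")
print("basis='leaves' would multiply by the 3% extraction yield.")
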