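"""Fit a Gibbs-Helmholtz stability curve through three free-energy points.

Builds a known curve (folding convention: dHm = -100 kcal/mol at
Tm = 350 K, dCp = -2 kcal/mol/K), observes dG at three temperatures, fits
the curve back and reads off the thermodynamic parameters.
"""

from thermocurve import StabilityCurve, fit_curve

true = StabilityCurve.from_params(dHm=-100.0, tm=350.0, dCp=-2.0)
points = [(t, true.evaluate(t)) for t in (318.15, 338.15, 358.15)]
print("observed (T K, dG kcal/mol):")
for t, dg in points:
    print(f"  {t:.2f}  {dg:+.3f}")

fit = fit_curve(points)
print(f"\nrecovered: dHm = {fit.dHm:.3f} kcal/mol, "
      f"Tm = {fit.tm:.3f} K ({fit.tm - 273.15:.2f} C), "
      f"dCp = {fit.dCp:.3f} kcal/mol/K")
print(f"maximal stability at Ts = {fit.ts - 273.15:.2f} C, "
      f"dG(25 C) = {fit.evaluate(298.15):+.2f} kcal/mol")
print("\nWith exactly three distinct temperatures the least-squares fit "
      "interpolates, so the true parameters are recovered to machine "
      "precision; with noisy points the same call returns the best-fit "
      "curve.")
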