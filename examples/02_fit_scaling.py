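"""Fit the urban area-population power law A = alpha * P**beta per division.

The fitted exponent beta also fixes the within-urban density gradient
lambda = 2 - 2*beta used by the desirability weights.
"""

from dasypop import GridSpec, WorldConfig, generate_world

# a wide single-division world gives the fit a decent sample of cities
world = generate_world(
    WorldConfig(grid=GridSpec(180, 180), n_divisions=1, counties_per_division=36, seed=7)
)
fits = world.study.ensure_scaling_fits()

print("division   alpha      beta   lambda   n    r^2")
for div, f in sorted(fits.items()):
    print(f"  D{div}     {f.alpha:8.5f}  {f.beta:5.3f}   {f.lambda_:5.3f}  {f.n_fit:3d}  {f.r_squared:5.3f}")
print("\nThe generator drew every footprint around beta = 0.95; the OLS fit")
print("on log10 area vs log10 population recovers it (small samples scatter).")
print("beta < 1 means bigger cities are denser: lambda = 2 - 2*beta > 0, so")
print("urban density decays with distance from the center as r^-lambda.")
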