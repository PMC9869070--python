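"""Derive the linear surrogate GWP equations and validate them.

The full emission model is exactly affine in (A, E, L, D_V) once the
volatile-corrected pathway is used, so OLS on any cohort recovers the
surrogate coefficients exactly (R^2 = 1). Fitted, analytically composed and
published coefficient sets are printed side by side, along with the maximum
absolute residual of each surrogate against the full equations.
"""

import pandas as pd

from silagegwp import (
    analytic_coefficients,
    compute_breakdowns,
    fit_linear_gwp,
    generate_mock_cohort,
    printed_coefficients,
    validate_surrogate,
)

frame = compute_breakdowns(generate_mock_cohort(n=1000, seed=0).frame)

for horizon in (20, 100):
    sets = [fit_linear_gwp(frame, horizon),
            analytic_coefficients(horizon=horizon),
            printed_coefficients(horizon)]
    table = pd.DataFrame([c.__dict__ for c in sets]).set_index("provenance")
    print(f"\nGWP{horizon} surrogate (mg CO2e per kg DM; inputs in mg/kg):")
    print(table[["intercept", "slope_a", "slope_e", "slope_l", "slope_n",
                 "slope_dv"]].round(5).to_string())
    for c in sets:
        res = validate_surrogate(frame, c)
        print(f"  max |full - {c.provenance}| over the cohort: {res:.3g} mg/kg")

print("\nThe ~29 mg/kg residual of the published set is a constant intercept")
print("offset; slopes agree with the analytic composition at all printed digits.")
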