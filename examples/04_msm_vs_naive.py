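"""Recover a known protective effect that naive analysis misses.

Runs the full pipeline on the protective scenario (true relapse hazard
ratio 0.5 under confounding by indication) and contrasts the weighted
marginal structural Cox estimate with the unweighted one.
"""

from msmtrial import AnalysisConfig, run_analysis

config = AnalysisConfig(
    scenario="protective",
    n_patients=2000,
    design="A",
    outcomes=("relapse", "worsening", "improvement"),
    seed=5,
)
result = run_analysis(config)

print("true effects: relapse HR 0.5, worsening HR 0.55, improvement HR 1.3\n")
for _, row in result.results.iterrows():
    label = "MSM   " if row["term"] == "treated" else "naive "
    print(
        f"{row['outcome']:12s} {label} HR {row['hazard_ratio']:.3f} "
        f"({row['ci_lower']:.3f}-{row['ci_upper']:.3f})"
    )
print(
    "\nThe sicker-patients-get-treated selection pulls the naive relapse "
    "HR toward 1; the stabilized weights restore the protective effect."
)
print("weight diagnostics:", {k: round(v, 3) for k, v in
                              result.diagnostics["weights"].items()})
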