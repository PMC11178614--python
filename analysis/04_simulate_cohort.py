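"""Simulate the survival cohort the statistical stage analyzes.

500 subjects under a proportional-hazards model with a log-hazard of
0.0012 per mL of MTV, correlated marrow infiltration, 20% high-risk
cytogenetics, administrative censoring at 110 months plus 10% dropout.
Also derives ISS / R-ISS stages per subject.
"""

from pathlib import Path

from bmquant import CohortConfig, generate_cohort, iss_stage, r_iss_stage, spearman_corr
from bmquant.pipeline import write_table

RESULTS = Path("results")
SEED = 20260928


def main() -> None:
    cohort = generate_cohort(CohortConfig(n_subjects=500, seed=SEED))
    cohort["iss"] = [iss_stage(b, a) for b, a in
                     zip(cohort.b2m_mg_l, cohort.albumin_g_dl)]
    cohort["r_iss"] = [r_iss_stage(i, bool(c), bool(l)) for i, c, l in
                       zip(cohort.iss, cohort.high_risk_cyto, cohort.ldh_high)]
    write_table(cohort, RESULTS / "cohort.csv")
    rho, p = spearman_corr(cohort.mtv_ml, cohort.infiltration_pct)
    print(f"n={len(cohort)}, events={int(cohort.event.sum())}, "
          f"median MTV {cohort.mtv_ml.median():.1f} mL, "
          f"Spearman(MTV, infiltration) rho={rho:.2f} (p={p:.1e}), "
          f"ISS I/II/III = {list(cohort.iss.value_counts().sort_index())}")


if __name__ == "__main__":
    main()
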