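"""Validate the measurements: ANCOVA of whole-brain and regional measures.

Tests the effects of gestational age, sex, and residual brain volume on
whole-brain subplate thickness / area / volume, then the repeated-measures
model of regional thickness with region and hemisphere as within-subject
factors (and region x GA, region x hemisphere interactions). Strong GA and
residual-volume effects with minimal sex effects reproduce the expected
scaling structure of the synthetic cohort. Outputs: results/ancova/*.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from fetalsp.cohort import CohortConfig, generate_cohort
from fetalsp.pipeline import whole_brain_ancova
from fetalsp.residualize import residualize
from fetalsp.stats import ancova


def load_cohort(path: Path, seed: int):
    if (path / "measures.csv").exists():
        return (pd.read_csv(path / "subjects.csv"),
                pd.read_csv(path / "measures.csv"))
    res = generate_cohort(CohortConfig(seed=seed))
    return res.subjects, res.measures


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    ap.add_argument("--out", type=Path, default=Path("results/ancova"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)
    subjects, measures = load_cohort(args.cohort, args.seed)

    wb = whole_brain_ancova(subjects, measures)
    for metric, res in wb.items():
        res.table.to_csv(args.out / f"whole_brain_{metric}.csv")
        ga = res.table.loc["ga_weeks"]
        rbv = res.table.loc["rbv"]
        print(f"whole-brain {metric:9s}: GA F={ga['F']:9.1f} "
              f"eta2={ga['partial_eta_sq']:.3f} | residual volume "
              f"F={rbv['F']:7.1f} eta2={rbv['partial_eta_sq']:.3f}")

    # regional thickness: repeated-measures with within-subject factors
    sub = subjects.set_index("subject_id")
    thick = measures.query("metric == 'thickness'").copy()
    thick["ga_weeks"] = sub.loc[thick.subject_id, "ga_weeks"].to_numpy()
    rbv = residualize(sub["brain_volume_mm3"].to_numpy(),
                      [(sub["ga_weeks"].to_numpy(), None)]).residuals
    thick["rbv"] = pd.Series(rbv, index=sub.index).loc[
        thick.subject_id].to_numpy()
    rm = ancova(thick, response="value", covariates=["ga_weeks", "rbv"],
                factors=["region", "hemisphere"], subject="subject_id",
                within=["region", "hemisphere"],
                interactions=[("region", "ga_weeks"),
                              ("region", "hemisphere")])
    rm.table.to_csv(args.out / "regional_thickness_rm.csv")
    print("\nregional thickness (repeated measures):")
    for eff in ("region", "region:ga_weeks", "region:hemisphere"):
        row = rm.table.loc[eff]
        print(f"  {eff:20s} F={row['F']:8.2f} p={row['p']:.2e} "
              f"eta2={row['partial_eta_sq']:.4f} [{rm.stratum[eff]}]")
    print(f"\nwrote ANCOVA tables to {args.out}/")


if __name__ == "__main__":
    main()
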