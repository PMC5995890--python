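"""Train the fractional-cover random forest on quadrat labels.

Assembles the training table (dropping protocol-violating quadrats), fits
the pooled regressor plus one model per sensor group, and reports internal
(out-of-bag) versus independent hold-out validation.  Writes the validation
table to results/cover_model_validation.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from woodycover.cover import assemble_training, fit_cover_regressor
from woodycover.metrics import build_metric_cube
from woodycover.synthetic import default_config, generate_covariates, generate_true_cover, sample_quadrats, simulate_scenes

ROOT = Path(__file__).resolve().parents[1]


def main(seed: int = 1, out_dir: Path = ROOT / "results") -> pd.DataFrame:
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = default_config(seed=seed)
    state = generate_true_cover(generate_covariates(cfg), cfg)
    cube = build_metric_cube(simulate_scenes(state), cfg.epochs)
    quads = sample_quadrats(state, 2000, seed=seed + 10, uncertain_frac=0.02, date_violation_frac=0.02)
    table = assemble_training(quads, cube, cfg.epochs, cfg.obs.sensor_by_epoch)
    print(f"Training table: {len(table.data)} rows "
          f"(dropped {table.dropped['date']} by date rule, "
          f"{table.dropped['uncertain']} uncertain, "
          f"{table.dropped['missing_metrics']} without metrics)")

    rows = []
    for group in ("all", "TM", "ETM"):
        reg = fit_cover_regressor(table, sensor_group=group, n_estimators=300, seed=seed)
        rows.append(
            {
                "sensor_group": group,
                "n_train": reg.n_train,
                "n_holdout": reg.n_holdout,
                "oob_r2": round(reg.oob_r2, 4),
                "holdout_r2": round(reg.holdout_r2, 4),
                "holdout_rmse": round(reg.holdout_rmse, 4),
            }
        )
        print(f"  {group:>4}: OOB R2 {reg.oob_r2:.3f}, hold-out R2 {reg.holdout_r2:.3f} "
              f"(RMSE {reg.holdout_rmse:.3f}, n={reg.n_train}+{reg.n_holdout})")
    out = pd.DataFrame(rows)
    out.to_csv(out_dir / "cover_model_validation.csv", index=False)
    return out


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    main(seed=ap.parse_args().seed)
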