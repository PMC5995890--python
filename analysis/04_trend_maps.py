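"""Predict cover per epoch, estimate per-pixel trends and quality weights.

Runs the full cover pipeline (simulate -> mask -> metrics -> regress ->
predict -> OLS trend), compares estimated against true slopes, checks the
logit-scale robustness variant, and derives the cell-level quality weights
used by the driver model.  Writes results/trend_summary.json.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from woodycover.pipeline import run_cover_pipeline
from woodycover.trends import logit_trend

ROOT = Path(__file__).resolve().parents[1]


def main(seed: int = 1, out_dir: Path = ROOT / "results") -> dict:
    out_dir.mkdir(parents=True, exist_ok=True)
    res = run_cover_pipeline(seed=seed)
    cfg = res.config

    lg = logit_trend(res.cover_pred, cfg.epoch_midpoints)
    ok = ~np.isnan(res.trend.slope) & ~np.isnan(lg.slope)
    sign_agree = float(
        (np.sign(res.trend.slope[ok]) == np.sign(lg.slope[ok])).mean()
    )
    sig = res.trend.pvalue < 0.05
    summary = {
        "seed": seed,
        "slope_truth_r": round(res.slope_truth_r, 4),
        "holdout_r2": round(res.regressor.holdout_r2, 4),
        "mean_estimated_slope": float(np.nanmean(res.trend.slope)),
        "fraction_significant_gain": float(np.nanmean(sig & (res.trend.slope > 0))),
        "fraction_significant_loss": float(np.nanmean(sig & (res.trend.slope < 0))),
        "logit_raw_sign_agreement": round(sign_agree, 4),
        "cells_excluded_by_quality": int(res.weights.excluded.sum()),
        "n_cells": int(res.weights.score.size),
    }
    (out_dir / "trend_summary.json").write_text(json.dumps(summary, indent=2))
    print(f"Estimated slopes correlate with truth at r = {res.slope_truth_r:.3f}")
    print(f"  mean slope {summary['mean_estimated_slope']:+.4f} /yr; "
          f"significant gain {summary['fraction_significant_gain']:.0%}, "
          f"loss {summary['fraction_significant_loss']:.0%}")
    print(f"  raw/logit slope sign agreement {sign_agree:.0%}; "
          f"{summary['cells_excluded_by_quality']}/{summary['n_cells']} cells excluded by quality")
    return summary


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    main(seed=ap.parse_args().seed)
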