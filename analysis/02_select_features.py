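"""Bayesian variable selection for contact-intensity and fatigue determinants.

Fits the regularized-horseshoe selection model to first-time participants
of two analysis waves, the sign-constrained half-RHS fatigue model to the
repeating participants of the same waves, and reports the union of the
per-wave selections — the two-wave robustness design of the emulated
study.
"""

import argparse
import json
import warnings
from pathlib import Path

import contactfatigue as cf
from contactfatigue.data_model import build_design, read_records


def select_for_wave(ds, seed):
    intensity = cf.fit_intensity_selection_model(ds, seed=seed,
                                                 n_warmup=3000, n_steps=2000)
    sel_int = cf.select_features(intensity)
    refit = cf.fit_intensity_refit_model(ds, selected=sel_int.selected,
                                         seed=seed + 1, n_warmup=1500, n_steps=1000)
    fatigue = cf.fit_fatigue_selection_model(ds, refit, seed=seed + 2,
                                             n_warmup=3000, n_steps=2000)
    sel_fat = cf.select_fatigue_features(fatigue)
    return intensity, sel_int, fatigue, sel_fat


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--records", type=Path,
                    default=Path("results/cohort/processed_records.csv"))
    ap.add_argument("--waves", type=int, nargs=2, default=[4, 8],
                    help="the two analysis waves (need first-timers and repeaters)")
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/selection"))
    args = ap.parse_args()
    warnings.filterwarnings("ignore", category=RuntimeWarning)

    rec = read_records(args.records)
    args.out.mkdir(parents=True, exist_ok=True)

    per_wave_int, per_wave_fat = [], []
    for i, w in enumerate(args.waves):
        sub = rec[rec["wave"] == w].reset_index(drop=True)
        ds = build_design(sub)
        meta = ds.metadata()
        print(f"wave {w}: {meta['n_first_time']} first-time, "
              f"{meta['n_repeating']} repeating participants")
        intensity, sel_int, fatigue, sel_fat = select_for_wave(ds, args.seed + 10 * i)
        intensity.table.to_csv(args.out / f"intensity_posterior_wave{w}.csv")
        fatigue.table.to_csv(args.out / f"fatigue_posterior_wave{w}.csv")
        per_wave_int.append(sel_int)
        per_wave_fat.append(sel_fat)
        print(f"  intensity features selected: {sorted(sel_int.selected)}")
        print(f"  fatigue features selected:   {sorted(sel_fat.selected)}")

    labels = [f"wave{w}" for w in args.waves]
    union_int = cf.union_across_waves(per_wave_int, labels)
    union_fat = cf.union_across_waves(per_wave_fat, labels)
    payload = {
        "intensity_selected": sorted(union_int.selected),
        "fatigue_selected": sorted(union_fat.selected),
        "intensity_per_wave": {k: sorted(v) for k, v in union_int.provenance.items()},
        "fatigue_per_wave": {k: sorted(v) for k, v in union_fat.provenance.items()},
        "thresholds": {"lower": union_int.thresholds[0],
                       "upper": union_int.thresholds[1]},
    }
    with open(args.out / "selection.json", "w") as fh:
        json.dump(payload, fh, indent=2)
    print(f"union across waves -> intensity: {payload['intensity_selected']}")
    print(f"union across waves -> fatigue:   {payload['fatigue_selected']}")


if __name__ == "__main__":
    main()
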