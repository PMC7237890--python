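"""Per-track motility of the simulated cohorts: mean velocity, straightness,
and displacement-vs-√time curves per compartment, mirroring the standard
intravital readouts (per-animal dots, across-animal mean ± SEM).

Reads results/cohorts/ (run 01 first); writes results/motility/.
"""

import argparse
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from perivax.motility import cohort_summary, displacement_curve, track_metrics
from perivax.render import read_tracks


def main(in_dir="results/cohorts", out_dir="results/motility") -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    fig, ax = plt.subplots(figsize=(5, 4))
    for path in sorted(Path(in_dir).glob("tracks_*.csv")):
        preset = path.stem.replace("tracks_", "")
        tab = read_tracks(path)
        rec = track_metrics(tab)
        rec.to_csv(out / f"metrics_{preset}.csv", index=False)
        summ = cohort_summary(rec, group_by="animal")
        for _, r in summ.iterrows():
            rows.append({"preset": preset, **r.to_dict()})
        try:
            curve = displacement_curve(tab, horizon=10.0)
            ax.plot(curve.sqrt_t, curve.mean_displacement, label=preset)
        except ValueError:
            pass
        v = summ.set_index("metric").loc["mean_velocity"]
        s = summ.set_index("metric").loc["straightness"]
        print(f"{preset:15s} velocity {v['mean']:6.2f} ± {v['sem']:.2f} µm/min   "
              f"straightness {s['mean']:.3f} ± {s['sem']:.3f}")
    pd.DataFrame(rows).to_csv(out / "summary.csv", index=False)
    ax.set_xlabel("sqrt(time) (min$^{1/2}$)")
    ax.set_ylabel("mean displacement (µm)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(out / "displacement_curves.png", dpi=120)
    print(f"summary -> {out / 'summary.csv'}")


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--in-dir", default="results/cohorts")
    ap.add_argument("--out", default="results/motility")
    a = ap.parse_args()
    main(a.in_dir, a.out)
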