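"""Binary toward/away T-zone classification per cohort: per-animal fractions
and across-animal mean ± SD. The control preset should show strongly
one-directional migration toward the T zone; CCR7-KO and LPS should sit near
0.5.

Reads results/cohorts/; writes results/directionality/.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from perivax.direction import classify_table, fraction_toward
from perivax.geometry import Geometry
from perivax.render import read_tracks


def main(in_dir="results/cohorts", out_dir="results/directionality") -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(Path(in_dir) / "geometry.json") as f:
        geometry = Geometry.from_dict(json.load(f)["geometry"])
    rows = []
    for path in sorted(Path(in_dir).glob("tracks_*.csv")):
        preset = path.stem.replace("tracks_", "")
        tab = read_tracks(path)
        res = classify_table(tab, geometry)
        res.to_csv(out / f"classified_{preset}.csv", index=False)
        if (res["class"] != "excluded").sum() == 0:
            print(f"{preset:15s} no classifiable tracks (all excluded)")
            continue
        frac = fraction_toward(res, group_by="animal")
        rows.append({"preset": preset, "mean_fraction_toward": frac.attrs["mean"],
                     "sd": frac.attrs["sd"], "n_animals": len(frac)})
        print(f"{preset:15s} fraction toward = {frac.attrs['mean']:.3f} "
              f"± {frac.attrs['sd']:.3f} (n={len(frac)} animals)")
    pd.DataFrame(rows).to_csv(out / "summary.csv", index=False)


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--in-dir", default="results/cohorts")
    ap.add_argument("--out", default="results/directionality")
    a = ap.parse_args()
    main(a.in_dir, a.out)
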