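#!/usr/bin/env python
"""Diel and seasonal activity dynamics from the classified capture stream.

Reads the per-trial activity profiles written by 03_field_trials.py (average
hourly sensor count per month per genus) and reports the recovered activity
peaks: the synthetic *Aedes* population is bimodal (dawn/dusk), *Culex*
nocturnal/crepuscular.  Writes a tidy combined table to
results/field/activity_profiles.csv.
"""

from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    frames = []
    for trial in (1, 2):
        path = ROOT / "results" / "field" / f"trial{trial}" / "activity_profile.csv"
        if not path.exists():
            raise SystemExit("run analysis/03_field_trials.py first")
        df = pd.read_csv(path)
        df["trial"] = trial
        frames.append(df)
    prof = pd.concat(frames, ignore_index=True)

    for (trial, genus), grp in prof.groupby(["trial", "genus"]):
        hourly = grp.groupby("hour")["mean_count"].mean()
        peaks = hourly.nlargest(3)
        peak_str = ", ".join(f"{h:02d}:00 ({v:.2f}/h)" for h, v in peaks.items())
        print(f"trial {trial} {genus}: top hourly activity {peak_str}")

    out = ROOT / "results" / "field" / "activity_profiles.csv"
    prof.to_csv(out, index=False)
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
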