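#!/usr/bin/env python
"""Simulate the two-rater feature ratings for a 137-clip stimulus set.

Writes the long-format rating table and the rating diagnostics (per-feature
inter-rater r, between-feature correlation matrix) that the downstream
regressor construction consumes, and prints the calibration summary: with the
default generator the two raters agree at r ~ 0.78 and the fourteen features
stay weakly inter-correlated (mean |r| ~ 0.18).
"""

import argparse
from pathlib import Path

from socmap import io, synth
from socmap.pipeline import build_session


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()
    out = args.out_dir
    out.mkdir(parents=True, exist_ok=True)

    sample = synth.generate_ratings(seed=args.seed)
    tracks = {(c, f, "A"): t for (c, f), t in sample.tracks_a.items()}
    tracks.update({(c, f, "B"): t for (c, f), t in sample.tracks_b.items()})
    io.write_rating_table(tracks, out / "ratings.tsv")

    session = build_session(args.seed)
    d = session.diagnostics
    io.save_json({"interrater_r": d["interrater_r"],
                  "interrater_mean_r": d["interrater_mean_r"],
                  "mean_abs_feature_r": d["mean_abs_feature_r"]},
                 out / "rating_diagnostics.json")
    d["feature_corr"].round(4).to_csv(out / "feature_correlations.tsv",
                                      sep="\t")

    print(f"wrote {len(sample.clip_ids)} clips x {len(sample.features)} "
          f"features x 2 raters -> {out / 'ratings.tsv'}")
    print(f"mean inter-rater r = {d['interrater_mean_r']:.3f} "
          f"(target ~0.78)")
    print(f"mean between-feature |r| = {d['mean_abs_feature_r']:.3f} "
          f"(target ~0.18)")


if __name__ == "__main__":
    main()
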