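#!/usr/bin/env python
"""Score the simulated screen and classify every strain.

Relative growth ratios are graded onto the ordinal scale, summed over
the 3 concentrations x 2 replicates, and thresholded at final score >= 3
(sensitive) / <= -2 (resistant).  Reports hit counts and, because the
screen is synthetic, the confusion-matrix recovery of the planted
classes.  Writes results/screen/screen_results.tsv and plate_qc.tsv.
"""

from pathlib import Path

from cgscreen import io
from cgscreen.scoring import confusion_metrics, score_screen

OUT = Path(__file__).resolve().parent.parent / "results" / "screen"

if __name__ == "__main__":
    growth = io.read_growth_table(OUT / "growth.tsv")
    truth = io.read_truth_table(OUT / "truth.tsv")
    layouts = io.read_plate_maps(OUT / "plate_maps.tsv")
    results, qc = score_screen(growth, layouts)
    io.write_results_table(results, OUT / "screen_results.tsv")
    qc.to_frame().to_csv(OUT / "plate_qc.tsv", sep="\t", index=False)
    counts = results["classification"].value_counts().to_dict()
    print(f"classification counts: {counts}")
    print(f"plate QC: {len(qc.passed)} plate/replicate pairs passed, "
          f"{len(qc.failed)} failed, {len(qc.unevaluable)} unevaluable")
    m = confusion_metrics(truth, results)
    print(f"recovery vs ground truth: sensitivity {m['sensitivity']:.3f}, "
          f"specificity {m['specificity']:.3f}, resistant recall {m['resistant_recall']:.3f}")
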