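#!/usr/bin/env python
"""Validate the screen's sensitive hits in simulated liquid culture.

A subset of sensitive hits is regrown in liquid medium with drug; the
endpoint OD600 yields the Net Treated Growth Value (NTGV), and strains
with NTGV <= 0.7 validate as sensitive.  Writes
results/validation/ntgv_results.tsv.
"""

from pathlib import Path

from cgscreen import io
from cgscreen.ntgv import ntgv_table
from cgscreen.synth import SimConfig, simulate_od600

SCREEN = Path(__file__).resolve().parent.parent / "results" / "screen"
OUT = Path(__file__).resolve().parent.parent / "results" / "validation"

if __name__ == "__main__":
    truth = io.read_truth_table(SCREEN / "truth.tsv")
    results = io.read_results_table(SCREEN / "screen_results.tsv")
    hits = results.loc[results["classification"] == "sensitive", "strain_id"]
    tested = truth[truth["strain_id"].isin(hits)].head(72)
    cfg = SimConfig(seed=1)
    od = simulate_od600(cfg, tested)
    nt = ntgv_table(od)
    OUT.mkdir(parents=True, exist_ok=True)
    io.write_od_table(od, OUT / "od600.tsv")
    nt.to_csv(OUT / "ntgv_results.tsv", sep="\t", index=False)
    n_tested = nt["strain_id"].nunique()
    n_val = int((nt["classification"] == "sensitive").sum())
    print(f"{n_val} of {n_tested} tested sensitive hits validate at NTGV <= 0.7")
    print(f"median NTGV of validated strains: "
          f"{nt.loc[nt['classification'] == 'sensitive', 'ntgv'].median():.3f}")
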