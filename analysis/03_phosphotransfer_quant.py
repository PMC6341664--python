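"""Phosphotransfer gel quantification: percent-of-wild-type activity.

Simulates replicate band-intensity tables for the H+4 substitution panel
at the reported activity levels (phospho-acceptance from the upstream
receiver domain, and phosphorelay through to the downstream one), then
quantifies them: per-replicate normalisation to the wild-type lane, mean
± sample SD across replicates. The qualitative picture — small residues
(S, A) near wild type, large/charged residues (V, L, E) nearly dead, Q
intermediate for acceptance but dead for relay — is the functional side
of the conservation census.

Writes results/activity_phosphorylation.tsv and results/activity_phosphorelay.tsv.
"""

import argparse
from pathlib import Path

import hptkit as h
from hptkit.assay_quant import activity_table
from hptkit.reference_data import ACTIVITY_TABLE_PERCENT

RESULTS = Path(__file__).resolve().parent.parent / "results"


def quantify(levels: dict[str, float], sds: dict[str, float], seed: int):
    df = h.generate_gel_lanes(h.GelDesign(
        levels=levels, n_replicates=3, level_sds=sds, seed=seed,
    ))
    return activity_table(h.percent_of_wildtype(df, "WT"))


def main(seed: int = 1) -> None:
    RESULTS.mkdir(exist_ok=True)
    accept = {v: t[0] for v, t in ACTIVITY_TABLE_PERCENT.items()}
    accept_sd = {v: t[1] for v, t in ACTIVITY_TABLE_PERCENT.items()}
    relay = {v: t[2] for v, t in ACTIVITY_TABLE_PERCENT.items()}
    relay_sd = {v: t[3] for v, t in ACTIVITY_TABLE_PERCENT.items()}

    t1 = quantify(accept, accept_sd, seed)
    t1.to_csv(RESULTS / "activity_phosphorylation.tsv", sep="\t", index=False)
    print("phospho-acceptance from the upstream receiver domain (% of WT):")
    print(t1.to_string(index=False))

    t2 = quantify(relay, relay_sd, seed + 1)
    t2.to_csv(RESULTS / "activity_phosphorelay.tsv", sep="\t", index=False)
    print("\nphosphorelay to the downstream receiver domain (% of WT):")
    print(t2.to_string(index=False))


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    main(**vars(ap.parse_args()))
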