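"""Ligand-depletion Kd fits for the HPt:receiver-domain interaction.

Simulates three replicate fluorescence titrations per protein variant at
the reported dissociation constants (receptor ~15.8 nM, titrant 10 nM to
6 uM, 1% multiplicative intensity noise), normalises each against its
buffer series and fits the quadratic ligand-depletion isotherm, reporting
mean Kd ± SD over replicates — the same summary convention used for
replicate titrations. Also runs a 100-replicate parameter-recovery study
at the wild-type-like Kd.

Writes results/binding_fits.tsv and results/binding_recovery.tsv.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

import hptkit as h
from hptkit.reference_data import KD_TABLE_UM, RECEPTOR_TOTAL_M

RESULTS = Path(__file__).resolve().parent.parent / "results"


def fit_variant(kd_um: float, seeds) -> tuple[float, float]:
    fits = []
    for s in seeds:
        lig, buf, _ = h.generate_titration(h.TitrationDesign(
            Kd=kd_um * 1e-6, receptor_total=RECEPTOR_TOTAL_M,
            noise_sd=0.01, n_points=20, seed=int(s),
        ))
        fits.append(h.fit_binding(h.normalize_titration(lig, buf)))
    return h.replicate_kd_summary(fits)


def main(seed: int = 1) -> None:
    RESULTS.mkdir(exist_ok=True)
    rng = np.random.default_rng(seed)

    rows = []
    for variant, (kd_um, _sd_reported) in KD_TABLE_UM.items():
        mean, sd = fit_variant(kd_um, rng.integers(0, 2**31 - 1, size=3))
        rows.append((variant, kd_um, mean * 1e6, sd * 1e6))
        print(f"{variant:5s} design Kd {kd_um:4.2f} uM -> "
              f"fitted {mean * 1e6:.2f} ± {sd * 1e6:.2f} uM (3 replicates)")
    pd.DataFrame(
        rows, columns=["variant", "design_Kd_uM", "fit_Kd_uM", "fit_sd_uM"]
    ).to_csv(RESULTS / "binding_fits.tsv", sep="\t", index=False)

    kds = []
    for s in range(100):
        lig, buf, _ = h.generate_titration(h.TitrationDesign(
            noise_sd=0.01, n_points=20, seed=seed * 1000 + s
        ))
        fit = h.fit_binding(h.normalize_titration(lig, buf))
        if fit.converged:
            kds.append(fit.params.Kd * 1e6)
    med = float(np.median(kds))
    print(f"\nrecovery study (Kd 0.94 uM, 1% noise, 100 replicates): "
          f"median {med:.3f} uM, IQR {np.percentile(kds, 25):.3f}-"
          f"{np.percentile(kds, 75):.3f} uM")
    pd.DataFrame({"replicate": range(len(kds)), "Kd_uM": kds}).to_csv(
        RESULTS / "binding_recovery.tsv", sep="\t", index=False
    )


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    main(**vars(ap.parse_args()))
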