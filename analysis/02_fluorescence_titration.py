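"""Depletion-isotherm fluorescence titrations of PADI4 with the importins.

Simulates the two titration scenarios (micromolar K_d, 3 µM fixed cargo,
1% signal noise) and fits the quadratic ligand-depletion model, showing
that the fits recover the generating dissociation constants with
sub-micromolar standard errors.
"""

import json
from pathlib import Path

from bindlab import synthetic_data as syn
from bindlab import titration as tit
from bindlab.io import write_titration_csv

RESULTS = Path(__file__).resolve().parents[1] / "results"
RESULTS.mkdir(exist_ok=True)
SEED = 2024


def main() -> None:
    out = {}
    for name in ("padi4_impa3_fluorescence", "padi4_dimpa3_fluorescence"):
        truth = syn.SCENARIOS[name]
        series, _ = syn.gen_titration(truth, noise_sd=0.5, seed=SEED)
        write_titration_csv(series, RESULTS / f"{name}.csv")
        fit = tit.fit_titration(series)
        out[name] = {
            "kd_true_uM": truth["kd"],
            "kd_fit_uM": round(fit.kd, 2),
            "kd_se_uM": round(fit.uncertainties["kd"], 2),
            "f0": round(fit.f0, 2),
            "dfmax": round(fit.dfmax, 2),
        }
    (RESULTS / "titration_fits.json").write_text(json.dumps(out, indent=2) + "\n")
    print(json.dumps(out, indent=2))


if __name__ == "__main__":
    main()
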