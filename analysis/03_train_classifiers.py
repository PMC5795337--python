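#!/usr/bin/env python
"""Train and evaluate PLS-DA, RBFNN, and SVM on the selected variables.

Loads the filtered dataset, split, and selection from steps 01-02
(regenerating if missing) and trains the three classifiers on the
calibration set restricted to the selected wavelengths, with their
standard tuning protocols: PLS-DA latent variables by leave-one-out CV,
RBFNN spread over the 0.1..1/1..100 grid, SVM (C, gamma) over integer
powers of two in [2^-8, 2^8].  SVM and RBFNN are also trained on the full
20,937-variable spectra for comparison (PLS-DA's LOO protocol is
impractically slow at full spectral width and is reported for the
selected variables only).

Writes results/model_accuracies.csv with per-class and total accuracy for
calibration and prediction sets, one row per model and feature mode.
"""

import subprocess
import sys
from pathlib import Path

import numpy as np
import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"
SEED = 1

from libsid import models as M

sys.path.insert(0, str(ROOT / "analysis"))
import importlib

load_filtered = importlib.import_module("02_select_lines").load_filtered


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    filtered = load_filtered()
    if not (SCRATCH / "split.npz").exists() or not (RESULTS / "selected_lines.csv").exists():
        subprocess.run([sys.executable, str(ROOT / "analysis" / "02_select_lines.py")], check=True)
    z = np.load(SCRATCH / "split.npz")
    cal, pred = filtered.subset(z["calibration"]), filtered.subset(z["prediction"])
    sel = pd.read_csv(RESULTS / "selected_lines.csv")["index"].to_numpy(dtype=int)
    print(f"{cal.n_shots} calibration / {pred.n_shots} prediction spectra, "
          f"{sel.size} selected variables")

    configs = {
        "plsda": M.PLSDAConfig(),
        "rbfnn": M.RBFNNConfig(),
        "svm": M.SVMConfig(grid_step_log2=1.0),
    }
    rows = []
    for mode in ("selected", "full_spectrum"):
        if mode == "selected":
            Xc, Xp = cal.intensities[:, sel], pred.intensities[:, sel]
            names = ["plsda", "rbfnn", "svm"]
        else:
            Xc, Xp = cal.intensities, pred.intensities
            names = ["rbfnn", "svm"]
        yc, yp = cal.varieties, pred.varieties
        for name in names:
            print(f"training {name} ({mode}, {Xc.shape[1]} variables) ...")
            if name == "plsda":
                model = M.train_plsda(Xc, yc, configs[name])
            elif name == "rbfnn":
                model = M.train_rbfnn(Xc, yc, configs[name], random_state=SEED)
            else:
                model = M.train_svm(Xc, yc, configs[name], random_state=SEED)
            report = M.evaluate(model, (Xc, yc), (Xp, yp))
            hyper = {k: v for k, v in model.hyperparameters.items() if k != "selection_accuracy"}
            row = report.to_frame(name).iloc[0].to_dict()
            row.update({"feature_mode": mode, "hyperparameters": str(hyper)})
            rows.append(row)
            print(f"  {name}: tuned {hyper}; calibration {report.total_calibration:.2f}% / "
                  f"prediction {report.total_prediction:.2f}%")

    table = pd.DataFrame(rows)
    table.to_csv(RESULTS / "model_accuracies.csv", index=False)
    print("\n", table.to_string(index=False))


if __name__ == "__main__":
    main()
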