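#!/usr/bin/env python
"""Calibrate the optical readout against the electrical one.

For the 10 Hz trains of script 01, quantifies each pulse three ways —
eEPSC amplitude, tail-corrected per-pulse dF/F area, and deconvolved
release peak — normalizes each sequence to its first pulse, and fits
origin-constrained regressions of the optical measures on the electrical
one. Slopes near 1 with small mean squared distance to the identity say
the two readouts are linearly related measures of the same release.
A saturating reporter variant is injected as a positive control for
detecting nonlinearity.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

import synaptoglu as sg

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "results" / "dataset"
OUT = ROOT / "results"


def regression_dict(res: sg.RegressionResult) -> dict:
    return {"slope": res.slope, "r_squared": res.r_squared,
            "p_value": res.p_value, "d_identity": res.d_identity,
            "n_points": res.n_points}


def main() -> None:
    OUT.mkdir(exist_ok=True)
    manifest = json.loads((DATA / "manifest.json").read_text())
    report = {}
    for ca in ("2mM", "4mM"):
        cond = manifest["conditions"][ca]
        proto = sg.StimulusProtocol(np.array(cond["train10hz"]["times"]))
        tau = cond["kernel_tau_s"]

        epsc = sg.read_trace_csv(DATA / ca / "train10hz_epsc.csv",
                                 units=sg.Units.AMPERE)
        metrics = sg.measure_train(epsc, proto)
        dff = sg.read_trace_csv(DATA / ca / "train10hz_dff.csv",
                                units=sg.Units.DFF)
        aucs = sg.per_pulse_auc(dff, proto, tau=tau)
        dec = sg.linear_deconvolve(dff, tau)
        peaks, _ = sg.cumulative_release(dec, proto)

        res_auc, tab_auc = sg.compare_readouts(aucs, metrics.amplitude,
                                               normalize=True)
        res_dec, tab_dec = sg.compare_readouts(peaks, metrics.amplitude,
                                               normalize=True)
        tab_dec.assign(auc=tab_auc["optical"]).to_csv(
            OUT / f"readout_pairs_{ca}.csv", index=False)

        # positive control: saturating reporter on a common quantal scale
        released = np.array(cond["train10hz"]["released_quanta"])
        cfg = sg.SynthConfig.for_condition(ca, noise_frames=0.0)
        sat_dff = sg.render_fluorescence(
            sg.apply_saturation(released, 0.5 * released.max()), proto, cfg
        ).truth_dff
        lin_dff = sg.render_fluorescence(released, proto, cfg).truth_dff
        per_sat, _ = sg.cumulative_release(
            sg.linear_deconvolve(sat_dff, cfg.kernel.tau), proto)
        per_lin, _ = sg.cumulative_release(
            sg.linear_deconvolve(lin_dff, cfg.kernel.tau), proto)
        gain = per_lin[0] / released[0]
        res_sat, _ = sg.compare_readouts(per_sat / gain, released)

        report[ca] = {
            "auc_vs_epsc": regression_dict(res_auc),
            "deconvolved_vs_epsc": regression_dict(res_dec),
            "saturated_control": regression_dict(res_sat),
        }
        print(f"{ca}: AUC slope {res_auc.slope:.3f} (d {res_auc.d_identity:.4f}), "
              f"deconvolved slope {res_dec.slope:.3f} (d {res_dec.d_identity:.4f}), "
              f"saturated control slope {res_sat.slope:.3f}")
    (OUT / "optical_vs_electrical.json").write_text(json.dumps(report, indent=2))
    print(f"calibration report -> {OUT / 'optical_vs_electrical.json'}")


if __name__ == "__main__":
    main()
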