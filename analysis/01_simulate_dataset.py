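#!/usr/bin/env python
"""Generate the synthetic study dataset.

Builds ground-truthed recordings for both calcium conditions (2 mM and
4 mM, differing in reporter decay constant and release magnitude): a 60 s
spontaneous-event trace, paired-pulse and 25 @ 100 Hz evoked trains with
both electrophysiological and fluorescence readouts, a 10-stimulus 10 Hz
train, and a cup-ROI image stack. Everything downstream (scripts 02-05)
reads from results/dataset/.
"""

import json
from pathlib import Path

import numpy as np

import synaptoglu as sg
from synaptoglu.imaging import ImageStack

OUT = Path(__file__).resolve().parents[1] / "results" / "dataset"
SEED = 20240101


def condition_config(ca: str, seed: int) -> sg.SynthConfig:
    # 4 mM roughly doubles release probability at this synapse
    pool = sg.PoolModel(n_rrp=100, p_r=0.3 if ca == "2mM" else 0.55,
                        refill_rate=400.0, quantal_amp=127e-12,
                        quantal_tau=0.33e-3)
    return sg.SynthConfig.for_condition(ca, seed=seed, pool=pool,
                                        noise_ephys=5e-12, noise_frames=5.0,
                                        mini_rate=7.0)


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": SEED, "conditions": {}}
    for i, ca in enumerate(("2mM", "4mM")):
        cfg = condition_config(ca, SEED + i)
        rng = cfg.rng()
        cdir = OUT / ca
        cdir.mkdir(exist_ok=True)

        # spontaneous quantal events (quantal kinetics, not evoked kinetics)
        mini_cfg = sg.SynthConfig.for_condition(
            ca, seed=SEED + 10 + i,
            pool=sg.PoolModel(quantal_amp=127e-12, quantal_tau=0.145e-3),
            noise_ephys=5e-12, mini_rate=7.0)
        minis, truth = sg.simulate_minis(60.0, mini_cfg, mini_cfg.rng())
        sg.write_trace_csv(minis, cdir / "minis.csv")
        truth.to_csv(cdir / "minis_truth.csv", index=False)

        protocols = {
            "ppr10": sg.StimulusProtocol([0.0, 0.010]),
            "ppr100": sg.StimulusProtocol([0.0, 0.100]),
            "train100hz": sg.StimulusProtocol.regular(25, 100.0),
            "train10hz": sg.StimulusProtocol.regular(10, 10.0),
        }
        cond_manifest = {"kernel_tau_s": cfg.kernel.tau, "p_r": cfg.pool.p_r}
        for name, proto in protocols.items():
            rel = sg.simulate_pool_train(proto, cfg.pool, rng).released
            epsc, _ = sg.render_epsc(rel, proto, cfg, rng)
            sg.write_trace_csv(epsc, cdir / f"{name}_epsc.csv")
            fluo = sg.render_fluorescence(rel, proto, cfg, rng,
                                          image=(name == "train100hz"))
            sg.write_trace_csv(fluo.dff, cdir / f"{name}_dff.csv")
            if fluo.stack is not None:
                ImageStack(frames=fluo.stack, frame_dt=fluo.dff.dt,
                           pre_frames=fluo.pre_frames,
                           t0=fluo.dff.t0).to_tiff(cdir / f"{name}_stack.tif")
                np.save(cdir / f"{name}_truth_mask.npy", fluo.mask)
            cond_manifest[name] = {
                "times": proto.times.tolist(),
                "released_quanta": rel.tolist(),
                "pre_frames": fluo.pre_frames,
            }
        manifest["conditions"][ca] = cond_manifest
        print(f"{ca}: wrote minis + {len(protocols)} protocols to {cdir}")
    (OUT / "manifest.json").write_text(json.dumps(manifest, indent=2))
    print(f"manifest -> {OUT / 'manifest.json'}")


if __name__ == "__main__":
    main()
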