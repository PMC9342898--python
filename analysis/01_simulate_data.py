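#!/usr/bin/env python
"""Materialize every synthetic dataset the downstream analyses consume.

Writes stopped-flow traces, titrations, ATPase series, a two-channel
SMLM field and a 3D track table (CSV + truth sidecars) under
scratch/data/, using the default study conditions with one base seed.
The later numbered scripts regenerate the same data in memory from the
same seed, so this step exists to make the inputs inspectable and to
feed the command-line interface.
"""

from pathlib import Path
import json

import pandas as pd

from myovi import io
from myovi.synthetic_data import (
    GeneratorConfig,
    gen_atpase,
    gen_smlm,
    gen_stoppedflow,
    gen_titration,
    gen_tracks,
    write_csv_with_sidecar,
)

SEED = 2026
OUT = Path(__file__).resolve().parents[1] / "scratch" / "data"


def main() -> None:
    cfg = GeneratorConfig(seed=SEED)
    OUT.mkdir(parents=True, exist_ok=True)

    traces, truth = gen_stoppedflow(cfg)
    manifest = []
    for i, (tr, info) in enumerate(zip(traces, truth["per_trace"])):
        name = f"stoppedflow/trace_{i:03d}.csv"
        io.write_trace(tr, OUT / name)
        manifest.append({"file": name, "conc_uM": info["conc_uM"],
                         "replicate": info["replicate"]})
    pd.DataFrame(manifest).to_csv(OUT / "stoppedflow" / "manifest.csv", index=False)
    (OUT / "stoppedflow" / "truth.json").write_text(
        json.dumps({k: v for k, v in truth.items() if k != "per_trace"}, indent=2)
    )
    print(f"stopped-flow: {len(traces)} traces at {sorted({m['conc_uM'] for m in manifest})} uM")

    for construct in cfg.titration.Kd:
        series, t = gen_titration(cfg, construct)
        df = pd.DataFrame(
            {"acceptor_uM": series.acceptor_total,
             "intensity_raw": series.raw_intensity,
             "intensity_corrected": series.intensity}
        )
        write_csv_with_sidecar(df, OUT / f"titration_{construct}.csv", t)
    print(f"titrations: constructs {sorted(cfg.titration.Kd)}")

    for construct in cfg.atpase.kcat:
        series, t = gen_atpase(cfg, construct)
        df = pd.DataFrame({"actin_uM": series.actin_conc, "rate_per_s": series.rate})
        write_csv_with_sidecar(df, OUT / f"atpase_{construct}.csv", t)
    print(f"atpase: constructs {sorted(cfg.atpase.kcat)}")

    locs, t = gen_smlm(cfg)
    write_csv_with_sidecar(locs.data, OUT / "smlm_localizations.csv", t)
    (OUT / "smlm_roi.json").write_text(json.dumps(locs.roi.__geo_interface__))
    print(f"smlm: {len(locs.data)} localizations, planted fraction {t['clustered_fraction']}")

    df, t = gen_tracks(cfg)
    write_csv_with_sidecar(df, OUT / "tracks.csv",
                           {k: v for k, v in t.items() if k != "per_track"})
    print(f"tracks: {t['n_tracks']} x {t['n_frames']} frames at {t['dt_s']} s")


if __name__ == "__main__":
    main()
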