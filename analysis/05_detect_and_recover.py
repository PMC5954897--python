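#!/usr/bin/env python
"""Run the stall-detection pipeline on the demo dataset and score it.

Reads the traces written by 04_synthesize_traces.py, detects stalls and
event pairs blind to the truth, then scores event recall/precision, force
accuracy and pair-type confusion against the generator's ground truth.
Writes results/recovery_report.json and the detected events/pairs tables.
"""

import json
from pathlib import Path

import pandas as pd

from tugtrap.io import read_trace
from tugtrap.pipeline import analyze_trace, recovery_report

RESULTS = Path(__file__).resolve().parents[1] / "results"
DATASET = Path(__file__).resolve().parents[1] / "scratch" / "demo_dataset"


def main() -> None:
    if not DATASET.exists():
        raise SystemExit("run analysis/04_synthesize_traces.py first")
    truth = pd.read_csv(DATASET / "ground_truth.csv")
    stalls, pairs = [], []
    for path in sorted(DATASET.glob("synth-*.csv")):
        result = analyze_trace(read_trace(path))
        stalls.extend(result["stalls"])
        pairs.extend(result["pairs"])

    pd.DataFrame(
        [{"trace_id": s.trace_id, "direction": s.direction, "t_start": s.t_start,
          "t_end": s.t_end, "peak_force_pN": s.peak_force, "t_stall_s": s.t_stall}
         for s in stalls]
    ).to_csv(RESULTS / "detected_events.csv", index=False)
    pd.DataFrame(
        [{"trace_id": p.first.trace_id, "pair_type": p.pair_type,
          "inactive_s": p.inactive_duration, "is_rr": p.is_rr,
          "flyback_s": p.flyback_time} for p in pairs]
    ).to_csv(RESULTS / "detected_pairs.csv", index=False)

    rep = recovery_report(stalls, pairs, truth)
    print(f"events: recall {rep['event_recall']:.3f}, "
          f"precision {rep['event_precision']:.3f} "
          f"({rep['n_detected_events']} detected / {rep['n_truth_events']} true)")
    print(f"stall force relative error: median "
          f"{rep['force_relative_error_median']:.3%}, "
          f"95th percentile {rep['force_relative_error_p95']:.3%}")
    print(f"pair-type confusion diagonal: {rep['pair_diagonal_fraction']:.3f}; "
          f"rapid-reversal call agreement: {rep['rr_agreement']:.3f}")
    print("pair confusion (rows = truth, columns = detected):")
    print(rep["pair_confusion"])

    serializable = {k: (v.to_dict() if isinstance(v, pd.DataFrame) else v)
                    for k, v in rep.items()}
    (RESULTS / "recovery_report.json").write_text(
        json.dumps(serializable, indent=2)
    )
    print(f"wrote {RESULTS / 'recovery_report.json'}")


if __name__ == "__main__":
    main()
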