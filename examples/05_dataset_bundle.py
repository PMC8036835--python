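"""Write a study to disk as a dataset bundle and read it back.

The bundle mirrors the published repository layout: Rawdata/ holds one HDF5
IF cube per participant (radar config embedded), VitalSign/ the 125 Hz
reference waveforms and per-second rates, Participants/ the cohort CSV, with
a JSON manifest at the root.  Reading validates the structure without
touching cube payloads; extraction results are exported as per-participant
CSVs next to the reference files.
"""

import dataclasses
import tempfile
from pathlib import Path

import radarvitals as rv

config = dataclasses.replace(rv.table2_config(), n_rx=1)
with tempfile.TemporaryDirectory() as tmp:
    root = Path(tmp) / "child_vitals_bundle"
    bundle = rv.generate_study(3, config, 35.0, seed=5, root=root)
    print("bundle folders:", sorted(p.name for p in root.iterdir() if p.is_dir()))
    print("participants  :", bundle.participant_ids)

    reopened = rv.read_bundle(root)
    for pid in reopened.participant_ids:
        estimate = rv.extract_vitals(reopened.load_cube(pid))
        csv_path = rv.export_vitals_csv(estimate, reopened.vitals_csv_path(pid))
        print(f"P{pid:03d}: vitals -> {csv_path.name}, "
              f"{int(estimate.valid.sum())}/{len(estimate.times)} windows valid")
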