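#!/usr/bin/env python
"""Generate the default simulated delineation study and write it to disk.

Fourteen phantom cases (spheres, ellipsoids, irregular blobs, and two-lesion
configurations, tagged with overlapping recurrence subtypes) are each
delineated by 8 simulated radiologists, 6 GTV− and 6 GTV+ radiation
oncologists. Masks go to scratch/study/ as NIfTI plus a JSON manifest that
the downstream analysis scripts consume.
"""

import sys
from pathlib import Path

from contour_iov import simulate_study
from contour_iov.io import write_study
from contour_iov.synthetic import default_study_spec

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0
OUT = Path(__file__).resolve().parents[1] / "scratch" / "study"


def main() -> None:
    spec = default_study_spec(master_seed=SEED)
    cases = simulate_study(spec)
    manifest = write_study(cases, OUT, config={"master_seed": SEED})
    n_masks = sum(len(s) for c in cases for s in c.groups.values())
    print(f"simulated {len(cases)} cases, {n_masks} delineations (master seed {SEED})")
    for c in cases:
        counts = ", ".join(f"{g}={len(s)}" for g, s in sorted(c.groups.items()))
        print(f"  {c.case_id} [{'/'.join(c.subtypes)}]: {counts}, "
              f"truth {c.metadata['truth_volume_mm3']:.0f} mm^3")
    print(f"manifest: {manifest}")


if __name__ == "__main__":
    main()
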