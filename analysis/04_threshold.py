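#!/usr/bin/env python
"""Kinetic threshold inference: where does 5-IP7 stop repressing Pho4?

Fits the exponential 5-IP7 depletion of the vip1d-like fixture and the
logistic Pho4 relocation curve, then evaluates the decay at the relocation
half-maximum.  Also contrasts the wildtype's fast relocation.  Writes a
JSON fit report under results/kinetics/.
"""

import json
from pathlib import Path

from ippdyn import kinetics, synthetic

OUT = Path("results/kinetics")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    conc, reloc = synthetic.generate_relocation_timecourse(seed=0, strain="vip1d")
    decay = kinetics.fit_exponential_decay(conc["time_min"], conc["value"])
    logistic = kinetics.fit_logistic(reloc["time_min"], reloc["value"])
    est = kinetics.infer_threshold(decay, logistic)

    _, reloc_wt = synthetic.generate_relocation_timecourse(seed=0, strain="wt")
    logistic_wt = kinetics.fit_logistic(reloc_wt["time_min"], reloc_wt["value"])

    report = {
        "decay": {"c0_uM": decay.c0, "k_per_min": decay.k},
        "relocation_vip1d": {"t_half_min": logistic.t_half, "width_min": logistic.width},
        "relocation_wt": {"t_half_min": logistic_wt.t_half},
        "threshold_uM": est.threshold_um,
    }
    (OUT / "threshold.json").write_text(json.dumps(report, indent=2))

    print(f"5-IP7 decay: C0 = {decay.c0:.2f} uM, k = {decay.k:.5f} /min")
    print(f"Pho4 relocation half-maximum: vip1d {logistic.t_half:.1f} min, "
          f"wt {logistic_wt.t_half:.1f} min")
    print(f"Repressive 5-IP7 threshold: {est.threshold_um:.2f} uM")


if __name__ == "__main__":
    main()
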