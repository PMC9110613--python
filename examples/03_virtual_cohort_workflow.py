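"""Simulate a virtual cohort and run the adaptive dosimetry workflow.

Thirteen virtual patients follow the clinical schedule (three SPECT/CT
points at cycle 1, one 24 h point at cycles 2-4).  The workflow routes
each cycle to the best available estimator and tags every dose.
"""

import logging
import warnings

import numpy as np

logging.basicConfig(level=logging.ERROR)

from tridose import CohortSpec, WorkflowConfig, generate_cohort, run_workflow
from tridose.evaluation import odr_variation_coefficient
from tridose.fitting import Slot

spec = CohortSpec(n_patients=13, seed=1)
patients, truth = generate_cohort(spec)

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    doses = run_workflow(patients, WorkflowConfig(seed=0))

print("method routing:", doses.method_tag.value_counts().to_dict())
print("\nper-cycle dose medians by VOI (Gy):")
print(doses.groupby("voi")["dose_Gy"].median().round(2).to_string())

cvs = []
for pat in patients:
    for voi in spec.vois:
        odrs, acts = [], []
        for cyc in pat.cycles:
            pt = cyc.slot_point(voi, Slot.H24)
            if pt is not None:
                odrs.append(pt.odr)
                acts.append(cyc.injected_activity_mbq)
        if len(odrs) >= 2:
            cvs.append(odr_variation_coefficient(odrs, acts))
print(f"\nmedian inter-cycle 24 h ODR variation coefficient: "
      f"{np.median(cvs):.1f}% (activity-scaled)")
print("\nKidney doses land near 3 Gy/cycle and marrow surrogates near")
print("0.3 Gy/cycle; the CV reflects the configured inter-cycle variability.")
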