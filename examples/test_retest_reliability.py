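"""Simulate three visits and compute the test-retest reliability report.

The subject is re-scanned with fresh noise and a small repositioning per
visit; every visit runs through the full pipeline independently, and the
per-tract mean-FA tables feed the reliability statistics: per-tract COV,
the >5 %-in-either-erosion exclusion screen, ICC(3,1) with a bootstrap CI
and pairwise correlation across visits.
"""

import warnings

import pandas as pd

from diffseg.phantom import make_phantom, simulate_visits
from diffseg.pipeline import RunConfig, process_subject, run_reliability

truth, _ = make_phantom(seed=7)
sessions = simulate_visits(truth, n_visits=3)

frames = []
for v, sess in enumerate(sessions, start=1):
    cfg = RunConfig(subject="demo", visit=f"visit-{v}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = process_subject(
            sess.dwi, sess.gtab, sess.t1, truth.template, truth.atlas, cfg
        )
    frames.append(res.metrics)

metrics = pd.concat(frames, ignore_index=True)
tract_names = set(truth.atlas.names.values())
metrics = metrics[metrics["tract"].isin(tract_names)]

report = run_reliability(metrics, RunConfig(n_boot=2000, seed=7))

print("per-tract COV (%), erosion 1:")
print(report["cov_erode1"].to_string(index=False))
print()
print(f"kept tracts    : {report['kept']}")
print(f"excluded (>5 %): {report['excluded']}")
if "icc" in report:
    lo, hi = report["icc_boot"]["ci"]
    print(f"ICC(3,1)       : {report['icc']['icc']:.3f} "
          f"(bootstrap 95% CI {lo:.3f}-{hi:.3f})")
print()
print("Low COV for the large slab and higher COV for the small "
      "fornix-like tract reproduce the size-reliability relationship the "
      "exclusion screen is built on.")
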