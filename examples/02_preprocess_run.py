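"""Temporal preprocessing of one BOLD run, both pipeline variants.

The connectivity-mapping variant regresses out the global signal and leaves
the time series spatially unsmoothed; the seed-FC variant smooths the series
first and keeps the global signal.  Both discard the first 10 volumes,
scrub frames with framewise displacement above 0.5 mm, regress motion/WM/CSF
nuisance signals and band-pass to 0.01-0.1 Hz.
"""

import numpy as np

from wgbc import compute_fd, exceeds_motion_limits, generate_cohort
from wgbc import preprocess_for_fc, preprocess_for_wgbc
from wgbc.synthetic import demo_spec, generate_motion_trace

cohort = generate_cohort(demo_spec(n_per_group=1, grid=16, n_volumes=120, seed=3))
run, trace = cohort.runs[0], cohort.motion[0]

fd = compute_fd(trace)
print(f"run: {run.n_volumes} volumes, TR {run.tr} s")
print(f"median FD {np.median(fd.fd[1:]):.3f} mm, max {fd.fd.max():.3f} mm; "
      f"motion exclusion: {exceeds_motion_limits(trace)}")

for name, fn in (("wGBC variant", preprocess_for_wgbc), ("FC variant", preprocess_for_fc)):
    clean, keep = fn(run, trace, cohort.wm_mask, cohort.csf_mask)
    print(f"{name}: {clean.n_volumes} volumes kept ({(~keep).sum()} scrubbed); "
          f"residual sd {clean.data.std():.3f} (input sd {run.data.std():.3f})")

# a trace with planted spikes shows scrubbing at work
spiky = generate_motion_trace(120, 0.08, 5, spike_indices=[30, 31, 70])
clean, keep = preprocess_for_wgbc(run, spiky, cohort.wm_mask, cohort.csf_mask)
print(f"with 3 injected FD spikes: scrubbed frames at "
      f"{np.flatnonzero(~keep).tolist()} (indices are post-discard)")
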