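"""Countercurrent overshoot: uphill tracer transport driven by a
downhill flow of unlabelled sugar.

The inside (finite) bath is preloaded with 100 mmol/L unlabelled
ligand; the outside bath holds 1 mmol/L of fully labelled ligand.  The
inside labelled concentration transiently exceeds the outside level --
uphill movement -- before everything relaxes to equilibrium.  Both the
alternating carrier and the fixed-site chain with a dual-occupancy
exchange site show the effect; the plain chain (no exchange site) does
not."""

import numpy as np

from portersim import (
    MultisiteParams,
    build_multisite_chain,
    build_symmetric_carrier,
    run_counterflow,
)

settings = dict(inside_load=100.0, tracer_outside=1.0, inside_capacity=1.0)

for name, model, t_max in [
    ("alternating carrier", build_symmetric_carrier(), 300.0),
    ("fixed-site chain + exchange site",
     build_multisite_chain(MultisiteParams(exchange_site=True)), 60.0),
    ("fixed-site chain, no exchange site", build_multisite_chain(), 60.0),
]:
    res = run_counterflow(model, t_grid=np.linspace(0.0, t_max, 400), **settings)
    peak_t = res.t[np.argmax(res.label_ratio)]
    print(f"{name:38s} peak label ratio {res.overshoot:7.3f} "
          f"at t = {peak_t:6.1f} s (final {res.label_ratio[-1]:.3f})")

print("""
A peak ratio above 1 is the overshoot: labelled sugar accumulates
inside above its outside concentration while the unlabelled gradient
lasts, then the ratio decays back toward 1.  The plain chain moves each
isotope independently, so it can only approach 1 from below.""")
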