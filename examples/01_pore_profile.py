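"""Pore-radius profile of a two-state synthetic channel.

Builds the reference 12-helix bundle in its open and closed conformations,
profiles the pore with the probe-sphere walk, and classifies each state
against the hydrated chloride-ion radius window (1.6-1.9 Å).
"""

from porexlink import ConductanceCriteria, ProfileParams, ensemble_profile, locate_minimum
from porexlink.pore_profile import classify_conductance
from porexlink.synthetic_data import channel_segment_map, default_channel_spec, make_channel

spec = default_channel_spec()
segments = channel_segment_map(spec)
params = ProfileParams(seed=1, z_step=0.5)

for state in ("open", "closed"):
    ensemble, truth = make_channel(spec, state)
    profile = ensemble_profile(ensemble, params, segment_map=segments)
    z_min, r_min = locate_minimum(profile)
    verdict = classify_conductance(profile, ConductanceCriteria())
    print(
        f"{state:>6s} state: narrowest radius {r_min:.2f} Å at z={z_min:+.1f} Å "
        f"(analytic truth {truth.min_radius:.2f} Å) -> {verdict}"
    )

# The open state profiles to ~2.5 Å at the filter, wide enough for a hydrated
# Cl- ion (1.6-1.9 Å); the closed state pinches below 1 Å and blocks it.
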