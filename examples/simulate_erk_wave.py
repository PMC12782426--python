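"""Forward-simulate an optogenetic ERK wave crossing a 1D epithelium.

Runs the spring-particle chain under the two radius rules: the original
one (radius follows the instantaneous ERK level) and the modified one
(radius follows the ERK time derivative, mimicking the
differentiator-like response inferred from data), and compares the
transient wave-arrival artifact between them.
"""

from erkmech import reference_wave_simulation
from erkmech.spring import wave_response_summary

summaries = {}
for rule in ("instantaneous", "derivative"):
    traj = reference_wave_simulation(rule)
    summaries[rule] = s = wave_response_summary(traj)
    print(f"radius rule: {rule}")
    print(f"  cells measured (wave-crossed):   {s['n_cells_measured']}")
    print(f"  mean net displacement:           {s['mean_net_displacement']:+.3f} cell lengths")
    print(f"  mean arrival excursion (dip):    {s['excursion_amplitude']:.3f} cell lengths")

ratio = (
    summaries["derivative"]["excursion_amplitude"]
    / summaries["instantaneous"]["excursion_amplitude"]
)
print(f"excursion ratio derivative/instantaneous: {100 * ratio:.1f}%")
print("(the wave travels leftward; positive net displacement means cells "
      "migrate opposite to the wave, as observed in wounded epithelia. The "
      "dip is a transient co-wave movement on wave arrival — an artifact of "
      "the instantaneous rule that the derivative rule suppresses.)")
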