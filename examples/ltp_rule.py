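"""The LTP memory rule on a single NMDA compartment.

Walks the charge accumulator C through a burst of gated synaptic events
followed by silence, printing the memory multiplier M = 1 + ln(C+1)/6
and the "time of memory" log10(C+1) as they rise quickly and then decay
in slow FQ-sized steps.
"""

from hipposim.plasticity import PlasticityParams, memory_value, update_charge

params = PlasticityParams(FQ=1.0)
C = 0.0
print("phase      event                    C        M_mult   memory_time")

for i in range(25):  # 25 gated events at a 12 mV NMDA depolarization
    C = update_charge(C, M_head=-68.0, gated=True, params=params)
m = memory_value(C)
print(f"burst      25 gated arrivals  {C:8.3f}  {m.multiplier:8.4f}  {m.memory_time:8.4f}")

for step in range(1, 4):  # forgetting steps (one per simulated second)
    C = update_charge(C, M_head=-80.0, gated=False, params=params, decay_due=True)
    m = memory_value(C)
    print(f"silence    forgetting step {step}  {C:8.3f}  {m.multiplier:8.4f}  {m.memory_time:8.4f}")

print(
    "\nEach gated event adds exp(10*dV)-1 (dV in volts) to the charge; "
    "forgetting subtracts FQ only while C > FQ, so the weight gain decays "
    "far more slowly than it was acquired and never drops below 1x."
)
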