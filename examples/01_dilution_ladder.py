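"""The olfactometer's air-dilution ladder from its two flowmeter settings.

Stimulus intensity is the fraction of odor-line air in the total delivered
flow; the clean line is metered in L/min and converted x1000 to match the
odor line's cc/min.
"""

from olfthresh import concentration_from_flows, default_ladder

ladder = default_ladder()

print("step  odor cc/min  clean L/min  nominal %  flow-derived %")
for step in ladder:
    print(
        f"{step.step_number:>4}  {step.odor_flow:>11.0f}  {step.clean_flow:>11.2f}"
        f"  {step.nominal_fraction * 100:>8.0f}  {step.actual_fraction * 100:>13.2f}"
    )

print()
print("custom pair (500 cc/min, 4.5 L/min) ->",
      f"{concentration_from_flows(500, 4.5) * 100:.1f}% odor")
print("Each row is one staircase step; the flow-derived percent rounds to the")
print("nominal label, so threshold arithmetic can use the nominal fractions.")
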