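"""Design the serial-dilution network and verify its flow and dilution.

Builds the multiplexed device's hydraulic network from its design
constraints (inlet pressures, mixer resistance, 20/5/20 μl/min stream
rates, 1:9 dilution merges), forward-solves it, and prints the stream flows
and the concentration reaching each observation channel.
"""

from mcdkit import device, propagate_concentration, solve_flow

spec = device.design_mcd(p_dilution_mbar=100.0, p_cell_mbar=50.0)
flow = solve_flow(spec)
propagate_concentration(flow)

print("Observation-channel streams (μl/min):")
print(f"{'channel':>8} {'chemostimulus':>14} {'cells':>7} {'buffer':>7}")
for i in range(6):
    print(f"{i:>8} {flow.flows_ulmin[f'feed_{i}']:>14.4f} "
          f"{flow.flows_ulmin[f'cell_supply_{i}']:>7.4f} "
          f"{flow.flows_ulmin[f'sheath_supply_{i}']:>7.4f}")

print("\nSerial dilution (Ci/C0 of the chemostimulus stream):")
for i, c in enumerate(device.mcd_dilution_profile(flow)):
    print(f"  C{i}/C0 = {c:.3e}")

print("\nMixer throughputs (μl/min):")
for i in range(1, 5):
    print(f"  mixer {i}: {flow.flows_ulmin[f'mixer_{i}']:.3f}")

# The 20/5/20 streams realise the 4:1:4 width stratification; the dilution
# chain should read 10^-i for i = 0..4 and exactly 0 for the control.
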