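# Device configuration for the automated tissue processor.
# All fields are optional; unspecified values fall back to the defaults shown.
exchange_volume: 250        # mL delivered to the tissue container per step
tissue_capacity: 300        # mL
transfer_flow_rate: 10      # mL/s, gravity premix -> tissue fill
drain_time: 30              # s the bottom valve stays open
valve_actuation_latency: 2  # s
controller_tick: 0.1        # s, actuation time quantum
prefetch: true              # blend step k+1 during step k's soak
stocks:
  - {name: Water,   concentration_pct: 0,   pump_id: 1}
  - {name: EtOH70,  concentration_pct: 70,  pump_id: 2}
  - {name: EtOH100, concentration_pct: 100, pump_id: 3}
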