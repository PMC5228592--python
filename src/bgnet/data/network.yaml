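# Network composition at the 80,000-neuron reference scale, fan-in
# connection table and external-drive rate table.

reference_total: 80000

# Population sizes at the reference scale; smaller networks use the same
# fractions (absolute fan-ins are preserved when scaling down).
population_sizes:
  MSN_D1: 37971
  MSN_D2: 37971
  FSN:    1599
  STN:    388
  GPe_TA: 329
  GPe_TI: 988
  SNr:    754

# In-degree per postsynaptic neuron.  spatial_window counts are expressed in
# MSN-equivalents at the reference scale (the ~2800-MSN dendritic/axonal
# field, the ~540-MSN FSN axonal field) and are converted to eligible-pre
# counts on a 1-D index ring at build time.
connections:
  MSN_D1->MSN_D1: {fan_in: 364, spatial_window: 2800}
  MSN_D1->MSN_D2: {fan_in: 84,  spatial_window: 2800}
  MSN_D2->MSN_D1: {fan_in: 392, spatial_window: 2800}
  MSN_D2->MSN_D2: {fan_in: 504, spatial_window: 2800}
  FSN->MSN_D1:    {fan_in: 16,  spatial_window: 2800}
  FSN->MSN_D2:    {fan_in: 11,  spatial_window: 2800}
  FSN->FSN:       {fan_in: 10,  spatial_window: 540}
  GPe_TA->MSN_D1: {fan_in: 10}
  GPe_TA->MSN_D2: {fan_in: 10}
  GPe_TA->FSN:    {fan_in: 10}
  GPe_TI->FSN:    {fan_in: 10, pre_subpopulation: 0.1}
  MSN_D2->GPe_TI: {fan_in: 500}
  GPe_TA->GPe_TA: {fan_in: 5}
  GPe_TA->GPe_TI: {fan_in: 5}
  GPe_TI->GPe_TA: {fan_in: 25}
  GPe_TI->GPe_TI: {fan_in: 25}
  STN->GPe_TI:    {fan_in: 30}
  STN->GPe_TA:    {fan_in: 30}
  GPe_TI->STN:    {fan_in: 30}
  GPe_TI->SNr:    {fan_in: 32}
  MSN_D1->SNr:    {fan_in: 500}
  STN->SNr:       {fan_in: 30}

# External Poisson rates (Hz) per target neuron for the two cortical
# regimes, and the square-wave modulation amplitudes (fraction of the
# rate).  Slow-wave runs use a 1-Hz modulation in both dopamine
# conditions; activation runs add a 20-Hz beta modulation only in the
# dopamine-depleted condition.
drives:
  CTX->MSN_D1: {rate_slow_wave: 448.0,  rate_activation: 546.0,  amp_slow_wave: 0.11, amp_activation: 0.11}
  CTX->MSN_D2: {rate_slow_wave: 592.0,  rate_activation: 722.0,  amp_slow_wave: 0.11, amp_activation: 0.11}
  CTX->FSN:    {rate_slow_wave: 646.0,  rate_activation: 787.0,  amp_slow_wave: 0.11, amp_activation: 0.11}
  CTX->STN:    {rate_slow_wave: 170.0,  rate_activation: 250.0,  amp_slow_wave: 0.11, amp_activation: 0.35}
  EXT->GPe_TA: {rate_slow_wave: 100.0,  rate_activation: 200.0,  amp_slow_wave: 0.0,  amp_activation: 0.0}
  EXT->GPe_TI: {rate_slow_wave: 720.0,  rate_activation: 1530.0, amp_slow_wave: 0.0,  amp_activation: 0.0}
  EXT->SNr:    {rate_slow_wave: 1800.0, rate_activation: 1800.0, amp_slow_wave: 0.0,  amp_activation: 0.0}
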