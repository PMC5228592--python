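# Synaptic parameter catalogue, one row per connection, transcribing the
# basic-synapse and short-term-plasticity tables row for row.
# g0 nS, tau_syn ms, E_rev mV, delay ms.  `std` (short-term dynamics) rows
# carry the Tsodyks-Markram utilization U and recovery/facilitation time
# constants; absent std means a static synapse.

connections:
  MSN_D1->MSN_D1: {receptor: GABA, g0: 0.15,  tau_syn: 8.0,  E_rev: -74.0, delay: 1.7}
  MSN_D1->MSN_D2: {receptor: GABA, g0: 0.375, tau_syn: 8.0,  E_rev: -74.0, delay: 1.7}
  MSN_D2->MSN_D1: {receptor: GABA, g0: 0.45,  tau_syn: 8.0,  E_rev: -74.0, delay: 1.7}
  MSN_D2->MSN_D2: {receptor: GABA, g0: 0.35,  tau_syn: 8.0,  E_rev: -74.0, delay: 1.7}
  FSN->MSN_D1:    {receptor: GABA, g0: 6.0,   tau_syn: 11.0, E_rev: -74.0, delay: 1.7,
                   std: {U: 0.29, tau_rec: 902.0, tau_fac: 53.0}}
  FSN->MSN_D2:    {receptor: GABA, g0: 6.0,   tau_syn: 11.0, E_rev: -74.0, delay: 1.7,
                   std: {U: 0.29, tau_rec: 902.0, tau_fac: 53.0}}
  FSN->FSN:       {receptor: GABA, g0: 1.0,   tau_syn: 6.0,  E_rev: -74.0, delay: 1.7,
                   std: {U: 0.29, tau_rec: 902.0, tau_fac: 53.0}}
  GPe_TA->MSN_D1: {receptor: GABA, g0: 0.04,  tau_syn: 87.0, E_rev: -74.0, delay: 7.0}
  GPe_TA->MSN_D2: {receptor: GABA, g0: 0.08,  tau_syn: 76.0, E_rev: -74.0, delay: 7.0}
  GPe_TA->FSN:    {receptor: GABA, g0: 0.51,  tau_syn: 66.0, E_rev: -74.0, delay: 7.0,
                   std: {U: 0.29, tau_rec: 902.0, tau_fac: 53.0}}
  GPe_TI->FSN:    {receptor: GABA, g0: 2.0,   tau_syn: 17.0, E_rev: -74.0, delay: 7.0,
                   std: {U: 0.29, tau_rec: 902.0, tau_fac: 53.0}}
  MSN_D2->GPe_TI: {receptor: GABA, g0: 2.0,   tau_syn: 6.0,  E_rev: -65.0, delay: 7.0,
                   std: {U: 0.24, tau_rec: 11.0, tau_fac: 73.0}}
  GPe_TA->GPe_TA: {receptor: GABA, g0: 0.33,  tau_syn: 5.0,  E_rev: -65.0, delay: 1.0}
  GPe_TA->GPe_TI: {receptor: GABA, g0: 1.3,   tau_syn: 5.0,  E_rev: -65.0, delay: 1.0}
  GPe_TI->GPe_TA: {receptor: GABA, g0: 0.33,  tau_syn: 5.0,  E_rev: -65.0, delay: 1.0}
  GPe_TI->GPe_TI: {receptor: GABA, g0: 1.3,   tau_syn: 5.0,  E_rev: -65.0, delay: 1.0}
  STN->GPe_TI:    {receptor: AMPA, g0: 0.35,  tau_syn: 12.0, E_rev: 0.0,   delay: 2.0}
  STN->GPe_TA:    {receptor: AMPA, g0: 0.11,  tau_syn: 12.0, E_rev: 0.0,   delay: 2.0}
  GPe_TI->STN:    {receptor: GABA, g0: 0.08,  tau_syn: 8.0,  E_rev: -84.0, delay: 1.0}
  GPe_TI->SNr:    {receptor: GABA, g0: 76.0,  tau_syn: 2.1,  E_rev: -72.0, delay: 3.0,
                   std: {U: 0.196, tau_rec: 969.0, tau_fac: 0.0}}
  MSN_D1->SNr:    {receptor: GABA, g0: 2.0,   tau_syn: 5.2,  E_rev: -80.0, delay: 7.0,
                   std: {U: 0.0192, tau_rec: 623.0, tau_fac: 559.0}}
  STN->SNr:       {receptor: AMPA, g0: 0.91,  tau_syn: 12.0, E_rev: 0.0,   delay: 4.5,
                   std: {U: 0.35, tau_rec: 800.0, tau_fac: 0.0}}

# External Poisson drives; one event stream per target neuron, entering
# through the listed receptor components (cortical input to MSN and STN
# co-activates AMPA and NMDA).
drives:
  CTX->MSN_D1:
    - {receptor: AMPA, g0: 0.5,     tau_syn: 12.0,  E_rev: 0.0, delay: 2.5}
    - {receptor: NMDA, g0: 0.11,    tau_syn: 160.0, E_rev: 0.0, delay: 2.5}
  CTX->MSN_D2:
    - {receptor: AMPA, g0: 0.5,     tau_syn: 12.0,  E_rev: 0.0, delay: 2.5}
    - {receptor: NMDA, g0: 0.019,   tau_syn: 160.0, E_rev: 0.0, delay: 2.5}
  CTX->FSN:
    - {receptor: AMPA, g0: 0.5,     tau_syn: 12.0,  E_rev: 0.0, delay: 2.5}
  CTX->STN:
    - {receptor: AMPA, g0: 0.25,    tau_syn: 4.0,   E_rev: 0.0, delay: 2.5}
    - {receptor: NMDA, g0: 0.00625, tau_syn: 160.0, E_rev: 0.0, delay: 2.5}
  EXT->GPe_TA:
    - {receptor: AMPA, g0: 0.5,     tau_syn: 5.0,   E_rev: 0.0, delay: 5.0}
  EXT->GPe_TI:
    - {receptor: AMPA, g0: 0.5,     tau_syn: 5.0,   E_rev: 0.0, delay: 5.0}
  EXT->SNr:
    - {receptor: AMPA, g0: 0.5,     tau_syn: 5.0,   E_rev: 0.0, delay: 5.0}
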