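# Dopamine-occupancy modulation catalogue: every parameter scaled as
# p <- p * (1 + beta * (alpha - 0.8)).
#
# `target` paths:
#   synapse:<connection>:g0      peak conductance of an internal connection
#   drive:<drive>:<receptor>:g0  peak conductance of an external drive component
#   fan_in:<connection>          in-degree (rounded half-up, floored at 0)
#   neuron:<population>:<param>  neuron model parameter
#
# `constraint` records the experimental ratio/shift each beta was derived
# from (ratio = value at occupancy 0 over value at occupancy 1; shift in mV).

alpha0: 0.8

entries:
  - {target: "synapse:FSN->FSN:g0",       beta: -1.27, constraint: {ratio: 2.7}}
  - {target: "synapse:GPe_TA->FSN:g0",    beta: -0.53, constraint: {ratio: 1.6}}
  - {target: "synapse:GPe_TI->FSN:g0",    beta: -0.53, constraint: {ratio: 1.6}}
  - {target: "synapse:GPe_TA->GPe_TA:g0", beta: -0.83, constraint: {ratio: 2.0}}
  - {target: "synapse:GPe_TA->GPe_TI:g0", beta: -0.83, constraint: {ratio: 2.0}}
  - {target: "synapse:GPe_TI->GPe_TA:g0", beta: -0.83, constraint: {ratio: 2.0}}
  - {target: "synapse:GPe_TI->GPe_TI:g0", beta: -0.83, constraint: {ratio: 2.0}}
  - {target: "synapse:MSN_D2->GPe_TI:g0", beta: -0.83, constraint: {ratio: 2.0}}
  - {target: "synapse:STN->GPe_TI:g0",    beta: -0.45, constraint: {ratio: 1.5}}
  - {target: "synapse:STN->GPe_TA:g0",    beta: -0.45, constraint: {ratio: 1.5}}
  - {target: "drive:CTX->MSN_D1:NMDA:g0", beta: 1.04,  constraint: {ratio: 0.14}}
  - {target: "drive:CTX->MSN_D2:AMPA:g0", beta: -0.26, constraint: {ratio: 1.27}}
  - {target: "fan_in:FSN->MSN_D2",        beta: -0.90,
     constraint: {note: "2x at occupancy 0 vs basal 0.8; printed beta kept"}}
  - {target: "synapse:MSN_D1->MSN_D1:g0", beta: 0.88,  constraint: {ratio: 0.25}}
  - {target: "synapse:MSN_D1->MSN_D2:g0", beta: 0.88,  constraint: {ratio: 0.25}}
  - {target: "synapse:MSN_D2->MSN_D1:g0", beta: 0.88,  constraint: {ratio: 0.25}}
  - {target: "synapse:MSN_D2->MSN_D2:g0", beta: 0.88,  constraint: {ratio: 0.25}}
  - {target: "fan_in:MSN_D1->MSN_D1",     beta: 0.88,  constraint: {ratio: 0.25}}
  - {target: "fan_in:MSN_D1->MSN_D2",     beta: 0.88,  constraint: {ratio: 0.25}}
  - {target: "fan_in:MSN_D2->MSN_D1",     beta: 0.88,  constraint: {ratio: 0.25}}
  - {target: "fan_in:MSN_D2->MSN_D2",     beta: 0.88,  constraint: {ratio: 0.25}}
  - {target: "synapse:GPe_TA->MSN_D1:g0", beta: -1.22, constraint: {ratio: 2.6}}
  - {target: "synapse:GPe_TA->MSN_D2:g0", beta: -1.15, constraint: {ratio: 2.5}}
  - {target: "synapse:MSN_D1->SNr:g0",    beta: 0.56,  constraint: {ratio: 0.5}}
  - {target: "drive:CTX->STN:AMPA:g0",    beta: -0.45,
     constraint: {note: "printed beta kept; stated 2.5x ratio inconsistent"}}
  - {target: "drive:CTX->STN:NMDA:g0",    beta: -0.45,
     constraint: {note: "printed beta kept; stated 2.5x ratio inconsistent"}}
  - {target: "synapse:GPe_TI->STN:g0",    beta: -0.24, constraint: {ratio: 1.25}}
  - {target: "neuron:MSN_D1:v_r",         beta: 0.0296, constraint: {note: "KIR up-regulation by D1"}}
  - {target: "neuron:MSN_D1:d",           beta: -0.450, constraint: {note: "D1 effect on recovery increment"}}
  - {target: "neuron:FSN:v_r",            beta: -0.078, constraint: {shift_mV: -5.0}}
  - {target: "neuron:GPe_TA:E_L",         beta: -0.181, constraint: {shift_mV: -10.0}}
  - {target: "neuron:GPe_TI:E_L",         beta: -0.181, constraint: {shift_mV: -10.0}}
  - {target: "neuron:SNr:E_L",            beta: -0.0896, constraint: {shift_mV: -5.0}}
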