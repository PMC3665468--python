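"""Random index table for Saaty's consistency ratio.

Mean of (lambda_max - k)/(k - 1) over random reciprocal matrices with
upper-triangle entries uniform on the 17-point Saaty scale, estimated by
this package's own ahp.simulate_ri machinery (batched eigenvalues),
100000 replicates per k, generator seeds RI_SEED + k.
"""

RI_SEED = 20260921
RI_SIM_REPS = 100000

RI_TABLE = {
    3: 0.527554,
    4: 0.884785,
    5: 1.110294,
    6: 1.249521,
    7: 1.339583,
    8: 1.404572,
    9: 1.449690,
    10: 1.484782,
    11: 1.514232,
    12: 1.536929,
    13: 1.554011,
    14: 1.571120,
    15: 1.584201,
}
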