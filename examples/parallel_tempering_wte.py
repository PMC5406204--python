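"""Parallel tempering with a well-tempered-ensemble energy bias.

A 10-rung ladder (300-400 K) runs on the double-well landscape.  A
preliminary stage deposits a 1-D bias on the potential energy; frozen
and rescaled, it broadens the energy fluctuations of the production run.
The ladder tuner adjusts a geometric ladder toward a target exchange
rate, the protocol used to pick rung spacings before production.
"""

from contactfes.sampling import (
    BeadSystem,
    EngineParams,
    make_potential,
    precompute_energy_bias,
    run_pt_metad,
    tune_ladder,
)
from contactfes.synthetic import make_toy_chain

potential = make_potential("double_well_2d")
params = EngineParams(seed=11)  # default ladder: 300 ... 400 K, 10 rungs

table = precompute_energy_bias(potential, params, n_steps=10_000, scale=0.5)
table.write("wte_bias.txt")
print(f"frozen energy bias over [{table.energies[0]:.2f}, "
      f"{table.energies[-1]:.2f}] kcal/mol, applied at scale {table.scale}")

plain = run_pt_metad(potential, params, 20_000, deposit_hills=False)
wte = run_pt_metad(potential, params, 20_000, deposit_hills=False,
                   energy_bias=table)
print(f"exchange rate, unbiased PT: {plain.exchange_rate:.2f}")
print(f"exchange rate, with WTE:    {wte.exchange_rate:.2f}")

# ladder tuning on a bead system (enough degrees of freedom for exchange
# rates to depend visibly on rung spacing)
beads = BeadSystem(make_toy_chain(21, seed=1), stiffness=2.0)
tune_params = EngineParams(
    temperature_ladder=tuple(300.0 * 1.05**k for k in range(4)),
    seed=2, timestep=0.02, friction=20.0, exchange_stride=10)
ladder, rate = tune_ladder(beads, tune_params, target_rate=0.30,
                           tolerance=0.05, n_steps=1500)
print("tuned ladder (K):", [f"{t:.0f}" for t in ladder],
      f"-> exchange rate {rate:.2f} (target 0.30 ± 0.05)")
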