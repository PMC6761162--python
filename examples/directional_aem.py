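"""Test the net direction of microbial exchange along a transect with AEM.

A source-attenuation process (strong proximal community propagating
distally) should be called "forward"; a direction-free process with the
same amount of spatial structure should stay ambiguous.
"""

from colonscape.aem import chain_edges, compare_directions, hellinger
from colonscape.sim import simulate_directional_profile

sites = [f"b{b}" for b in range(1, 8)]
hypotheses = {
    "proximal_to_distal": (sites, chain_edges(sites)),
    "distal_to_proximal": (sites, chain_edges(sites[::-1])),
}

for mode in ("downstream", "exchangeable"):
    table, metadata = simulate_directional_profile(mode=mode, seed=3)
    result = compare_directions(
        hellinger(table.counts), metadata["site"], hypotheses,
        n_perm=199, seed=3,
    )
    print(f"{mode} process:")
    print(result.summary().round(3).to_string(index=False))
    print(f"  verdict: {result.verdict}\n")

print("The matched-size adjusted R2 is higher for the hypothesis whose "
      "leading eigenfunctions describe the data efficiently; with no true "
      "direction the two models tie and the verdict is ambiguous.")
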