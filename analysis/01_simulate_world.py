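"""Generate the default synthetic study world (seed 42) and write its files.

The world provides every input the later stages consume: a scale-free
interactome with a planted, densely interconnected core of longevity genes,
essentiality labels, an orthology map to a mirrored second species, RNAi
clone availability, and per-gene survival plus thrashing-assay data with
20 planted lifespan effects (12 long, 8 short) among the screened genes.
"""

from pathlib import Path

from longnet.synth import gen_world, write_world

OUT = Path("results/world")

world = gen_world(seed=42)
paths = write_world(world, OUT)

print(f"interactome: {world.interactome.n_nodes} genes, "
      f"{world.interactome.n_edges} interactions")
print(f"planted core: {len(world.true_core)} genes")
print(f"screened candidates: {len(world.candidates.candidates)} "
      f"({world.candidates.counts})")
print(f"planted effects: {len(world.effect_genes_long)} long, "
      f"{len(world.effect_genes_short)} short")
print(f"wrote {len(paths)} files to {OUT}/")
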