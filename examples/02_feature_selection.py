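"""Structural and physicochemical feature blocks with selection.

Computes 2048-bit Morgan fingerprints and the RDKit 2D descriptor block for
a small compound set, then applies the selection protocol: variance filter
at 0.05 on both blocks, pairwise-correlation filter at 0.95 (signed r,
greedy left-to-right) on the descriptors.
"""

from pkcascade import curation
from pkcascade.features import FeatureRecipe, morgan_matrix, physchem_block
from pkcascade.synthetic import SyntheticPKSpec, generate

_, human_raw, _ = generate(SyntheticPKSpec(n_human=120, n_animal=30, n_overlap=10, seed=2))
dataset, _ = curation.curate_dataset(human_raw, "human", curation.HUMAN_ENDPOINTS)
smiles = dataset.std_smiles

morgan = morgan_matrix(smiles)
phys = physchem_block(smiles)
print(f"raw Morgan block:     {morgan.matrix.shape[1]} bits")
print(f"raw descriptor block: {phys.matrix.shape[1]} descriptors")

recipe = FeatureRecipe().fit(smiles)
print(f"retained Morgan bits: {len(recipe.morgan_names)} (variance >= 0.05)")
print(f"retained descriptors: {len(recipe.physchem_names)} "
      f"(variance >= 0.05, pairwise r <= 0.95)")

fm = recipe.transform(smiles[:3])
print(f"assembled matrix for 3 compounds: {fm.matrix.shape}")
# Retained counts depend on the dataset's chemical diversity: bits set in
# almost all or almost no compounds carry no variance and are dropped.
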