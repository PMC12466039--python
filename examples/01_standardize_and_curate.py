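"""Standardize SMILES and curate a raw PK table.

Builds a tiny synthetic human PK table (with duplicates and salt forms),
then runs the curation protocol: standardization at pH 7.4, duplicate
merging by median, molecular-weight filtering, decadic log transform.
"""

from pkcascade import curation, standardize_smiles
from pkcascade.synthetic import SyntheticPKSpec, generate

# standardization: largest fragment, canonical tautomer, pH-7.4 protonation
for raw in ["CC(=O)O", "CCN.Cl", "OCC", "CC(N)C(=O)O"]:
    print(f"{raw:15s} -> {standardize_smiles(raw)}")

_, human_raw, _ = generate(
    SyntheticPKSpec(n_human=80, n_animal=30, n_overlap=10, seed=1,
                    duplicate_fraction=0.1, salt_fraction=0.1)
)
dataset, report = curation.curate_dataset(human_raw, "human", curation.HUMAN_ENDPOINTS)

print(f"\ninput records:        {report.n_input}")
print(f"unique after merge:   {report.n_after_merge}")
print(f"MW threshold:         {report.mw_threshold:.1f} Da "
      f"({report.n_mw_removed} removed)")
print(f"final compounds:      {report.n_final}")
print(f"sparsity:             {100 * report.sparsity:.2f}% missing cells")
print(f"log-transformed:      {sorted(dataset.log_transformed)} (fu stays raw)")
# The curated table has one row per unique standardized structure; VDss/CL/
# t1/2/MRT are log10 values ready for regression, fu stays a raw fraction.
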