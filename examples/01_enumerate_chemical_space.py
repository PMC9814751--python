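"""Build a small targeted chemical space by one-step virtual reactions.

Cores carrying carboxylic-acid or hydroxyl handles are coupled with small
substituents (amines, alcohols, alkyl halides, MW < 200) through amide
formation, esterification and Williamson ether synthesis; the union of the
accessible cores and the generated products is the search space MOLSPACE.
"""

from solucover import (REAL_SMILES_FIXTURE, build_molspace, enumerate_products,
                       filter_substituents)
from solucover.chemspace import _molecule_from_smiles

cores = [_molecule_from_smiles(smi, name, "accessible")
         for name, smi in REAL_SMILES_FIXTURE[:10]]
subs = [_molecule_from_smiles(smi, name, "substituent")
        for name, smi in REAL_SMILES_FIXTURE[10:]]
subs = filter_substituents(subs, mw_limit=200.0)

generated = enumerate_products(cores, subs, site_mode="all_sites")
molspace = build_molspace(cores, generated)

print(f"{len(cores)} accessible cores x {len(subs)} substituents")
print(f"-> {len(generated)} generated products, MOLSPACE of {len(molspace)}")
print("\nfirst products (canonical SMILES, provenance):")
for m in generated[:5]:
    p = m.provenance
    print(f"  {m.smiles:45s}  {p.core_id} + {p.substituent_id} [{p.reaction_id}]")
# Each product records which core, substituent and reaction produced it, so
# every virtual molecule maps back to a one-step synthesis recipe.
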