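"""Reversed allosteric effect: which residues feel the orthosteric ligand.

The same shell protein is modelled twice — without the ligand (apo) and
with a pseudo-node for the surface-bound ligand (holo) — and the RAE of
each pocket residue is the change of its in-pocket interaction pattern.
"""

import numpy as np

from allomap import (
    build_enm,
    cross_correlation,
    detect_pockets,
    interaction_matrix,
    residue_rae,
    top_rae_residue,
)
from allomap.fixtures import make_shell_structure

structure, _ = make_shell_structure(seed=0, ligand="surface")
ligand = structure.ligands[0]

c_apo = cross_correlation(build_enm(structure, None))
c_holo = cross_correlation(build_enm(structure, ligand))

pocket = detect_pockets(structure)[0]
profile = residue_rae(
    interaction_matrix(c_apo, pocket, "apo"),
    interaction_matrix(c_holo, pocket, "holo"),
)
order = np.argsort(-profile.rae)[:5]
print(f"pocket 0: {len(profile.residues)} lining residues, "
      f"pocket RAE = {profile.pocket_rae:.3f}")
print("top responders to the orthosteric perturbation:")
for k in order:
    print(f"  {profile.residues[k]}  RAE {profile.rae[k]:.4f}")
print("pathway sink (highest RAE):", top_rae_residue(profile))
# High-RAE residues are the predicted allosteric residues of the site;
# the top one becomes the endpoint of the regulation pathway.
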