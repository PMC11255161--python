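# Default physics constants for Lu-177 radioligand dosimetry (version 1).
# Key = value; '#' starts a comment.  Overridable via the run configuration.
#
# Physical half-life and mean electron (beta + conversion + Auger) energy
# per decay, ICRP Publication 107 values.
nuclide.name = Lu-177
nuclide.physical_half_life_h = 159.53
nuclide.electron_energy_per_decay_keV = 147.9

# Tissue densities, g/cm^3 (kidney parenchyma; lymph-node/soft-tissue
# lesions; bone lesions ~ cortical bone).
density.kidney = 1.06
density.lesion_soft = 1.03
density.lesion_bone = 1.92

# ICRP reference masses for a single salivary gland, g.
mass.parotid = 25.0
mass.submandibular = 12.5

# Proposed cumulative absorbed-dose limits for organs at risk, Gy.
limit.kidney_Gy = 28.0
limit.salivary_gland_Gy = 35.0
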