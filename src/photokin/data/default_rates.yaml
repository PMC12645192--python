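# Elementary rate constants for the photosensitization reaction network.
# No experimental values exist for these steps; every entry is an
# order-of-magnitude, literature-scale placeholder chosen once so that the
# simulator reproduces the qualitative behaviour of the system (first-order
# substrate loss, k_obs linear in sensitizer concentration, ~10x slower
# degradation without oxygen). Units: min^-1 (first order) and M^-1 min^-1
# (second order).
#
# Pseudo-first-order excitation of the sensitizer / ground-state complex
# (lamp photon flux x absorbed fraction / (volume x N_A x concentration)):
k_exc_rf: 50.0
k_exc_complex: 50.0
# Intersystem crossing and excited-singlet deactivation (ns-scale singlet,
# isc yield ~0.7):
k_isc: 6.0e9
k_singlet_decay: 2.0e9
# Intrinsic triplet deactivation, 1/lifetime for the ~17.5 us triplet
# measured without oxygen (the sub-microsecond aerobic lifetime emerges
# from oxygen quenching below):
k_triplet_decay: 3.4e6
# Type I: electron transfer from the triplet sensitizer to the substrate
# (~1e5 M^-1 s^-1), radical deprotonation, and diffusion-limited capture of
# the substrate radical by oxygen:
k_electron_transfer: 6.0e6
k_deprotonation: 1.0e6
k_radical_oxygen: 6.0e10
# Type II: near-diffusion-limited triplet quenching by oxygen (~1e9
# M^-1 s^-1) and singlet-oxygen chemistry (substrate attack ~1e7 M^-1 s^-1;
# relaxation 1/3.5 us in water):
k_oxygen_quench: 6.0e10
k_singlet_oxygen_attack: 6.0e8
k_singlet_oxygen_decay: 1.7e7
# Anaerobic complex route: fast association, slow H-abstraction branch in
# the triplet complex, diffusion-limited semiquinone disproportionation and
# radical recombination, slower reoxidation of the reduced flavin:
k_complex_formation: 6.0e8
k_h_abstraction: 1500.0
k_disproportionation: 6.0e10
k_rfh2_oxidation: 6.0e7
k_radical_recombination: 6.0e10
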