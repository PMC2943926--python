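# Default synthetic study design: 13 grylloblattodean genera (8 monotypic
# fossil + 5 extant holding 10/5/3/1/1 species = 28 specimens, 20 extant).
#
# Genus mean shapes are truncated Fourier radius perturbations of a circle,
# mean_coeffs = [a1, b1, a2, b2, a3, b3, a4, b4] in
#   r(theta) = r0 * (1 + sum_h a_h cos(h theta) + b_h sin(h theta)).
# Extant genera share a rounded-quadrate, bilaterally symmetric base shape
# (tight family cluster); fossil genera are mutually dispersed and distinct
# from the extant family. Minimum between-genus mean separation (~0.05 in
# coefficient space) is an order of magnitude above the per-coefficient
# within-genus standard deviation.
r0: 1.0
n_vertices: 400
k_semilandmarks: 50
within_genus_sd: 0.005
landmark_jitter_sd: 0.002
nuisance: true
genera:
  - name: Galloisiana
    status: extant
    n_species: 10
    mean_coeffs: [0.0, 0.0, 0.10, 0.0, 0.02, 0.0, 0.06, 0.0]
  - name: Grylloblatta
    status: extant
    n_species: 5
    mean_coeffs: [0.0, 0.0, 0.15, 0.0, 0.00, 0.0, 0.06, 0.0]
  - name: Grylloblattella
    status: extant
    n_species: 3
    mean_coeffs: [0.0, 0.0, 0.10, 0.0, 0.00, 0.0, 0.11, 0.0]
  - name: Grylloblattina
    status: extant
    n_species: 1
    mean_coeffs: [0.0, 0.0, 0.06, 0.0, 0.00, 0.0, 0.09, 0.0]
  - name: Namkungia
    status: extant
    n_species: 1
    mean_coeffs: [0.0, 0.0, 0.08, 0.0, -0.03, 0.0, 0.03, 0.0]
  - name: Blattogryllulus
    status: fossil
    n_species: 1
    mean_coeffs: [0.07, 0.0, -0.21, 0.0, 0.00, 0.0, 0.03, 0.0]
  - name: Parasheimia
    status: fossil
    n_species: 1
    mean_coeffs: [0.0, 0.07, 0.35, 0.0, 0.00, 0.0, -0.07, 0.0]
  - name: Plesioblattogryllus
    status: fossil
    n_species: 1
    mean_coeffs: [0.0, 0.0, 0.03, 0.21, 0.07, 0.0, 0.14, 0.0]
  - name: Sojanoraphidia
    status: fossil
    n_species: 1
    mean_coeffs: [-0.08, 0.0, -0.07, 0.0, 0.00, 0.17, 0.00, 0.0]
  - name: Sylvamicropteron
    status: fossil
    n_species: 1
    mean_coeffs: [0.0, 0.0, 0.42, 0.0, 0.00, 0.0, 0.11, 0.0]
  - name: Sylvonympha
    status: fossil
    n_species: 1
    mean_coeffs: [0.14, 0.14, 0.00, 0.0, -0.11, 0.0, 0.00, 0.0]
  - name: Tataronympha
    status: fossil
    n_species: 1
    mean_coeffs: [0.0, -0.11, 0.17, -0.14, 0.00, 0.0, 0.00, 0.08]
  - name: Tillyardembia
    status: fossil
    n_species: 1
    mean_coeffs: [-0.14, 0.0, 0.07, 0.0, 0.14, 0.0, -0.08, 0.0]
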