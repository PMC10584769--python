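# Default tractography protocols for the six clinically relevant tracts.
#
# Label references: name@ipsi / name@contra resolve to the _L/_R label of
# the hemisphere being built; name@both is the union; a bare name must
# match a (midline) label exactly.  All mm quantities are world mm.
#
# Tracking defaults shared by every tract: step 0.2 mm, curvature radius
# 1 mm, 10,000 attempts per seed voxel.  Amplitude cutoffs are fractions
# of the field's global maximum fODF amplitude.  rfbc_threshold is the
# post-tractography fiber-to-bundle-coherence cutoff (medium 1e-3,
# high 1e-1, or none).

tracts:
  CST:
    n_streamlines: 7500
    amplitude_cutoff_fraction: 0.07
    rfbc_threshold: 1.0e-3
    seed:
      op: axial_slab
      thickness_mm: 4
      reference: {op: select, labels: [fourth_ventricle]}
      of:
        op: split_axis
        axis: AP
        side: anterior
        fraction: 0.5
        of: {op: select, labels: ["brainstem@ipsi"]}
    targets:
      - {op: select, labels: ["precentral@ipsi"]}
    excludes:
      - {op: select, labels: ["brainstem@contra"]}
      - {op: select, labels: ["thalamus@ipsi"]}

  IFOF:
    n_streamlines: 15000
    amplitude_cutoff_fraction: 0.07
    rfbc_threshold: 1.0e-3
    seed:
      op: select
      labels: ["pars_triangularis@ipsi", "pars_opercularis@ipsi",
               "pars_orbitalis@ipsi", "anterior_orbital@ipsi",
               "posterior_orbital@ipsi", "frontal_pole@ipsi"]
    targets:
      - op: select
        labels: ["occipital_inferior@ipsi", "occipital_middle@ipsi",
                 "occipital_superior@ipsi"]
    includes:
      # capsula externa approximated by a small sphere in the white matter
      # between the posterior insular cortex and the putamen
      - op: sphere_between
        volume_mm3: 24
        a: {op: select, labels: ["posterior_insula@ipsi"]}
        b: {op: select, labels: ["putamen@ipsi"]}
        constraint: {op: select, labels: ["white_matter@ipsi"]}

  OR:
    n_streamlines: 7500
    amplitude_cutoff_fraction: 0.10
    rfbc_threshold: 1.0e-3
    seed_cone: lateral     # initial direction within a 45 deg half-angle cone
    seed:
      op: gaussian_dilate
      sigma_mm: 1.5
      of: {op: select, labels: ["lgn@ipsi"]}
    targets:
      - {op: select, labels: ["calcarine@ipsi"]}
    excludes:
      - {op: select, labels: ["precuneus@ipsi"]}
      - {op: select, labels: ["basal_forebrain@ipsi"]}
      - {op: select, labels: ["lingual@ipsi"]}

  AF:
    n_streamlines: 7500
    amplitude_cutoff_fraction: 0.075
    rfbc_threshold: 1.0e-3
    seed:
      op: union
      of:
        - {op: select, labels: ["pars_triangularis@ipsi", "pars_opercularis@ipsi"]}
        - op: split_axis   # ventral and inferior part of the precentral gyrus
          axis: IS
          side: inferior
          fraction: 0.5
          of: {op: select, labels: ["precentral@ipsi"]}
    targets:
      - op: split_axis     # middle and posterior part of the temporal gyri
        axis: AP
        side: posterior
        fraction: 0.3333333333
        of: {op: select, labels: ["superior_temporal@ipsi", "middle_temporal@ipsi"]}
    excludes:
      - {op: select, labels: ["putamen@ipsi"]}
      - {op: select, labels: ["anterior_insula@ipsi"]}
      - {op: select, labels: ["thalamus@ipsi"]}

  FAT:
    n_streamlines: 5000
    amplitude_cutoff_fraction: 0.09
    rfbc_threshold: 1.0e-3
    seed:
      # SMA + pre-SMA, bounded anteriorly by a vertical plane through the
      # genu of the corpus callosum
      op: split_by_plane
      keep: posterior
      of: {op: select, labels: ["smc@ipsi"]}
      landmark: {op: select, labels: [corpus_callosum]}
    targets:
      - {op: select, labels: ["pars_opercularis@ipsi", "pars_triangularis@ipsi"]}

  SLF3:
    n_streamlines: 7000
    amplitude_cutoff_fraction: 0.08
    rfbc_threshold: 1.0e-3
    seed:
      op: union
      of:
        - {op: select, labels: ["pars_triangularis@ipsi", "pars_opercularis@ipsi"]}
        - op: split_axis   # ventral precentral gyrus
          axis: IS
          side: inferior
          fraction: 0.5
          of: {op: select, labels: ["precentral@ipsi"]}
    targets:
      - {op: select, labels: ["supramarginal@ipsi"]}
    excludes:
      - {op: select, labels: ["angular@ipsi"]}
      - {op: select, labels: ["thalamus@ipsi"]}
      - op: gaussian_dilate   # slightly enlarged superior temporal gyrus,
        sigma_mm: 3.0         # restricted to the grey matter
        of: {op: select, labels: ["superior_temporal@ipsi"]}
        constraint:
          op: select
          labels: ["superior_temporal@ipsi", "middle_temporal@ipsi",
                   "supramarginal@ipsi", "angular@ipsi"]
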