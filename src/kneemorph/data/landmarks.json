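{
  "version": 1,
  "conventions": {
    "x": "mediolateral, +x lateral (right-knee convention, FLCP - FMCP)",
    "y": "anteroposterior, +y anterior",
    "z": "proximodistal, +z proximal"
  },
  "landmarks": [
    {"acronym": "FME", "bone": "femur", "name": "Femoral medial epicondyle", "description": "The anterior-distal osseous prominence over the medial aspect of the distal femur; refined as the locally most medial point (the prominence protrudes mediolaterally and anchors the femoral width).", "refine_axis": "x", "refine_sense": "min", "secondary_axis": null, "secondary_sense": null},
    {"acronym": "FLE", "bone": "femur", "name": "Femoral lateral epicondyle", "description": "The anterior-distal osseous prominence over the lateral aspect of the distal femur; refined as the locally most lateral point (the prominence protrudes mediolaterally and anchors the femoral width).", "refine_axis": "x", "refine_sense": "max", "secondary_axis": null, "secondary_sense": null},
    {"acronym": "FMCP", "bone": "femur", "name": "Femoral medial condyle posterior", "description": "The most posterior point of the medial condyle.", "refine_axis": "y", "refine_sense": "min", "secondary_axis": null, "secondary_sense": null},
    {"acronym": "FLCP", "bone": "femur", "name": "Femoral lateral condyle posterior", "description": "The most posterior point of the lateral condyle.", "refine_axis": "y", "refine_sense": "min", "secondary_axis": null, "secondary_sense": null},
    {"acronym": "FMCD", "bone": "femur", "name": "Femoral medial condyle distal", "description": "The most distal point of the medial condyle.", "refine_axis": "z", "refine_sense": "min", "secondary_axis": null, "secondary_sense": null},
    {"acronym": "FLCD", "bone": "femur", "name": "Femoral lateral condyle distal", "description": "The most distal point of the lateral condyle.", "refine_axis": "z", "refine_sense": "min", "secondary_axis": null, "secondary_sense": null},
    {"acronym": "FMTA", "bone": "femur", "name": "Femoral medial trochlea anterior", "description": "The most anterior point of the medial trochlea.", "refine_axis": "y", "refine_sense": "max", "secondary_axis": null, "secondary_sense": null},
    {"acronym": "FLTA", "bone": "femur", "name": "Femoral lateral trochlea anterior", "description": "The most anterior point of the lateral trochlea.", "refine_axis": "y", "refine_sense": "max", "secondary_axis": null, "secondary_sense": null},
    {"acronym": "FMCPP", "bone": "femur", "name": "Femoral medial condyle posterior proximal", "description": "The most proximal point of the cartilage at the posterior medial condyle; tied to a sagittal image view, propagated without extremum refinement.", "refine_axis": null, "refine_sense": null, "secondary_axis": null, "secondary_sense": null},
    {"acronym": "FLCPP", "bone": "femur", "name": "Femoral lateral condyle posterior proximal", "description": "The most proximal point of the cartilage at the posterior lateral condyle; tied to a sagittal image view, propagated without extremum refinement.", "refine_axis": null, "refine_sense": null, "secondary_axis": null, "secondary_sense": null},
    {"acronym": "Notch", "bone": "femur", "name": "Femoral notch", "description": "The most anterior point in the middle of the femoral notch (caudal-to-cranial view).", "refine_axis": "y", "refine_sense": "max", "secondary_axis": null, "secondary_sense": null},
    {"acronym": "FMCIP", "bone": "femur", "name": "Femoral medial condyle internal point", "description": "The most lateral point of the medial condyle cartilage at one third of the notch depth anteroposteriorly; constructed definition, propagated without extremum refinement.", "refine_axis": null, "refine_sense": null, "secondary_axis": null, "secondary_sense": null},
    {"acronym": "FMCEP", "bone": "femur", "name": "Femoral medial condyle external point", "description": "The most medial point of the medial condyle cartilage at one third of the notch depth anteroposteriorly; constructed definition, propagated without extremum refinement.", "refine_axis": null, "refine_sense": null, "secondary_axis": null, "secondary_sense": null},
    {"acronym": "FLCIP", "bone": "femur", "name": "Femoral lateral condyle internal point", "description": "The most medial point of the lateral condyle cartilage at one third of the notch depth anteroposteriorly; constructed definition, propagated without extremum refinement.", "refine_axis": null, "refine_sense": null, "secondary_axis": null, "secondary_sense": null},
    {"acronym": "FLCEP", "bone": "femur", "name": "Femoral lateral condyle external point", "description": "The most lateral point of the lateral condyle cartilage at one third of the notch depth anteroposteriorly; constructed definition, propagated without extremum refinement.", "refine_axis": null, "refine_sense": null, "secondary_axis": null, "secondary_sense": null},
    {"acronym": "TMIE", "bone": "tibia", "name": "Tibial medial intercondylar eminence", "description": "The most proximal (highest) point of the medial intercondylar eminence.", "refine_axis": "z", "refine_sense": "max", "secondary_axis": null, "secondary_sense": null},
    {"acronym": "TLIE", "bone": "tibia", "name": "Tibial lateral intercondylar eminence", "description": "The most proximal (highest) point of the lateral intercondylar eminence.", "refine_axis": "z", "refine_sense": "max", "secondary_axis": null, "secondary_sense": null},
    {"acronym": "TMCP", "bone": "tibia", "name": "Tibial medial condyle posterior", "description": "The most posterior and lateral point of the medial compartment.", "refine_axis": "y", "refine_sense": "min", "secondary_axis": "x", "secondary_sense": "max"},
    {"acronym": "TLCP", "bone": "tibia", "name": "Tibial lateral condyle posterior", "description": "The most posterior and medial point of the lateral compartment.", "refine_axis": "y", "refine_sense": "min", "secondary_axis": "x", "secondary_sense": "min"},
    {"acronym": "TMCM", "bone": "tibia", "name": "Tibial medial condyle medial", "description": "The most medial point of the tibial plateau, axially aligned following the posterior condylar line of the corresponding femur.", "refine_axis": "x", "refine_sense": "min", "secondary_axis": null, "secondary_sense": null},
    {"acronym": "TLCL", "bone": "tibia", "name": "Tibial lateral condyle lateral", "description": "The most lateral point of the tibial plateau, axially aligned following the posterior condylar line of the corresponding femur.", "refine_axis": "x", "refine_sense": "max", "secondary_axis": null, "secondary_sense": null},
    {"acronym": "TMCA", "bone": "tibia", "name": "Tibial medial condyle anterior", "description": "The most anterior point on the cartilage of the medial tibial plateau; tied to a sagittal image view, propagated without extremum refinement.", "refine_axis": null, "refine_sense": null, "secondary_axis": null, "secondary_sense": null},
    {"acronym": "TLCA", "bone": "tibia", "name": "Tibial lateral condyle anterior", "description": "The most anterior point on the cartilage of the lateral tibial plateau; tied to a sagittal image view, propagated without extremum refinement.", "refine_axis": null, "refine_sense": null, "secondary_axis": null, "secondary_sense": null}
  ]
}
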