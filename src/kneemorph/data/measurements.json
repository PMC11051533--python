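{
  "version": 1,
  "measurements": [
    {"abbreviation": "AP MFC", "description": "Anteroposterior size of the medial femoral condyle", "landmark_a": "FMCP", "landmark_b": "FMTA", "axis": "y", "alt_pair": null},
    {"abbreviation": "AP LFC", "description": "Anteroposterior size of the lateral femoral condyle", "landmark_a": "FLCP", "landmark_b": "FLTA", "axis": "y", "alt_pair": null},
    {"abbreviation": "AP notch", "description": "Anteroposterior size of the femoral notch", "landmark_a": "FMCP", "landmark_b": "Notch", "axis": "y", "alt_pair": ["FLCP", "Notch"]},
    {"abbreviation": "fML", "description": "Mediolateral size of the distal femur", "landmark_a": "FME", "landmark_b": "FLE", "axis": "x", "alt_pair": null},
    {"abbreviation": "ML MFC", "description": "Mediolateral size of the medial femoral condyle", "landmark_a": "FMCIP", "landmark_b": "FMCEP", "axis": "x", "alt_pair": null},
    {"abbreviation": "ML LFC", "description": "Mediolateral size of the lateral femoral condyle", "landmark_a": "FLCIP", "landmark_b": "FLCEP", "axis": "x", "alt_pair": null},
    {"abbreviation": "ML notch", "description": "Mediolateral size of the femoral notch", "landmark_a": "FMCIP", "landmark_b": "FLCIP", "axis": "x", "alt_pair": null},
    {"abbreviation": "PCL", "description": "Posterior condylar line", "landmark_a": "FMCP", "landmark_b": "FLCP", "axis": "x", "alt_pair": null},
    {"abbreviation": "PD MFC", "description": "Proximodistal size of the medial femoral condyle", "landmark_a": "FMCPP", "landmark_b": "FMCD", "axis": "z", "alt_pair": null},
    {"abbreviation": "PD LFC", "description": "Proximodistal size of the lateral femoral condyle", "landmark_a": "FLCPP", "landmark_b": "FLCD", "axis": "z", "alt_pair": null},
    {"abbreviation": "AP MTP", "description": "Anteroposterior size of the medial tibial plateau", "landmark_a": "TMCP", "landmark_b": "TMCA", "axis": "y", "alt_pair": null},
    {"abbreviation": "AP LTP", "description": "Anteroposterior size of the lateral tibial plateau", "landmark_a": "TLCP", "landmark_b": "TLCA", "axis": "y", "alt_pair": null},
    {"abbreviation": "tML", "description": "Mediolateral size of the tibial plateau", "landmark_a": "TMCM", "landmark_b": "TLCL", "axis": "x", "alt_pair": null},
    {"abbreviation": "ML MTP", "description": "Mediolateral size of the medial tibial plateau", "landmark_a": "TMCM", "landmark_b": "TMIE", "axis": "x", "alt_pair": null},
    {"abbreviation": "ML LTP", "description": "Mediolateral size of the lateral tibial plateau", "landmark_a": "TLCL", "landmark_b": "TLIE", "axis": "x", "alt_pair": null}
  ]
}
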