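{
  "description": "Reference per-class statistics for 15 commercial rice types imaged in a lightbox: per-grain means and spreads of the nine morpho-colorimetric descriptors, grain counts, and published stage/deployment accuracy summaries used for consistency checks.",
  "feature_names": ["FD", "Cir", "AR", "Ext", "APIdx", "L", "a", "b", "YI"],
  "classes": [
    {"class_id": 1,  "abbreviation": "KHO", "name": "Khoshihikari",        "category": "white", "grain_length": "short",  "n": 243,
     "mean": {"FD": 1.82, "Cir": 0.89, "AR": 1.63, "Ext": 0.72, "APIdx": 0.70, "L": 55.96, "a": 1.93,  "b": -1.61, "YI": -4.17},
     "sd":   {"FD": 0.08, "Cir": 0.02, "AR": 0.09, "Ext": 0.04, "APIdx": 0.08, "L": 1.61,  "a": 0.55,  "b": 1.81,  "YI": 4.69}},
    {"class_id": 2,  "abbreviation": "SRS", "name": "Sushi rice",          "category": "white", "grain_length": "short",  "n": 276,
     "mean": {"FD": 1.82, "Cir": 0.90, "AR": 1.64, "Ext": 0.72, "APIdx": 0.71, "L": 53.80, "a": 2.05,  "b": -0.91, "YI": -2.42},
     "sd":   {"FD": 0.08, "Cir": 0.02, "AR": 0.10, "Ext": 0.04, "APIdx": 0.08, "L": 1.81,  "a": 0.17,  "b": 0.42,  "YI": 1.12}},
    {"class_id": 3,  "abbreviation": "BMB", "name": "Bomba",               "category": "white", "grain_length": "short",  "n": 210,
     "mean": {"FD": 1.83, "Cir": 0.91, "AR": 1.61, "Ext": 0.73, "APIdx": 0.75, "L": 55.20, "a": 1.89,  "b": 0.70,  "YI": 1.78},
     "sd":   {"FD": 0.10, "Cir": 0.04, "AR": 0.11, "Ext": 0.05, "APIdx": 0.20, "L": 1.75,  "a": 0.38,  "b": 0.65,  "YI": 1.64}},
    {"class_id": 4,  "abbreviation": "CLP", "name": "Calasparra",          "category": "white", "grain_length": "short",  "n": 262,
     "mean": {"FD": 1.82, "Cir": 0.91, "AR": 1.58, "Ext": 0.74, "APIdx": 0.69, "L": 54.62, "a": 2.52,  "b": -0.34, "YI": -0.88},
     "sd":   {"FD": 0.12, "Cir": 0.08, "AR": 0.16, "Ext": 0.05, "APIdx": 0.31, "L": 2.09,  "a": 0.37,  "b": 0.40,  "YI": 1.05}},
    {"class_id": 5,  "abbreviation": "ARB", "name": "Arborio",             "category": "white", "grain_length": "medium", "n": 126,
     "mean": {"FD": 1.66, "Cir": 0.83, "AR": 1.94, "Ext": 0.67, "APIdx": 1.17, "L": 54.87, "a": 1.34,  "b": -0.16, "YI": -0.40},
     "sd":   {"FD": 0.04, "Cir": 0.02, "AR": 0.10, "Ext": 0.05, "APIdx": 0.10, "L": 1.71,  "a": 0.31,  "b": 0.82,  "YI": 2.16}},
    {"class_id": 6,  "abbreviation": "CLS", "name": "Calrose",             "category": "white", "grain_length": "medium", "n": 230,
     "mean": {"FD": 1.67, "Cir": 0.83, "AR": 1.97, "Ext": 0.68, "APIdx": 0.75, "L": 56.71, "a": 1.27,  "b": -0.35, "YI": -0.91},
     "sd":   {"FD": 0.18, "Cir": 0.04, "AR": 0.20, "Ext": 0.07, "APIdx": 0.07, "L": 3.31,  "a": 0.52,  "b": 1.01,  "YI": 2.52}},
    {"class_id": 7,  "abbreviation": "LGW", "name": "Long-grain",          "category": "white", "grain_length": "long",   "n": 195,
     "mean": {"FD": 1.57, "Cir": 0.61, "AR": 3.32, "Ext": 0.57, "APIdx": 0.46, "L": 59.39, "a": 1.31,  "b": -1.82, "YI": -4.38},
     "sd":   {"FD": 0.10, "Cir": 0.04, "AR": 0.34, "Ext": 0.13, "APIdx": 0.08, "L": 1.06,  "a": 0.19,  "b": 0.31,  "YI": 0.76}},
    {"class_id": 8,  "abbreviation": "JAS", "name": "Jasmine",             "category": "white", "grain_length": "long",   "n": 297,
     "mean": {"FD": 1.59, "Cir": 0.64, "AR": 3.18, "Ext": 0.59, "APIdx": 0.50, "L": 59.50, "a": 1.30,  "b": -1.43, "YI": -3.56},
     "sd":   {"FD": 0.10, "Cir": 0.09, "AR": 0.47, "Ext": 0.14, "APIdx": 0.21, "L": 3.41,  "a": 0.40,  "b": 0.36,  "YI": 0.50}},
    {"class_id": 9,  "abbreviation": "BAS", "name": "Basmati",             "category": "white", "grain_length": "long",   "n": 330,
     "mean": {"FD": 1.58, "Cir": 0.59, "AR": 3.59, "Ext": 0.55, "APIdx": 0.27, "L": 59.16, "a": 1.52,  "b": -1.53, "YI": -3.71},
     "sd":   {"FD": 0.17, "Cir": 0.11, "AR": 0.66, "Ext": 0.15, "APIdx": 0.18, "L": 1.47,  "a": 0.25,  "b": 1.60,  "YI": 3.87}},
    {"class_id": 10, "abbreviation": "BDM", "name": "Biodynamic rice",     "category": "whole", "grain_length": "medium", "n": 224,
     "mean": {"FD": 1.62, "Cir": 0.82, "AR": 2.06, "Ext": 0.69, "APIdx": 0.83, "L": 53.10, "a": 2.27,  "b": 3.91,  "YI": 10.55},
     "sd":   {"FD": 0.16, "Cir": 0.03, "AR": 0.18, "Ext": 0.08, "APIdx": 0.11, "L": 1.93,  "a": 0.30,  "b": 1.03,  "YI": 2.88}},
    {"class_id": 11, "abbreviation": "MGB", "name": "Medium grain brown",  "category": "whole", "grain_length": "medium", "n": 212,
     "mean": {"FD": 1.59, "Cir": 0.79, "AR": 2.27, "Ext": 0.60, "APIdx": 0.71, "L": 55.20, "a": 1.97,  "b": 4.72,  "YI": 12.22},
     "sd":   {"FD": 0.12, "Cir": 0.06, "AR": 0.26, "Ext": 0.10, "APIdx": 0.29, "L": 1.46,  "a": 0.27,  "b": 2.02,  "YI": 5.23}},
    {"class_id": 12, "abbreviation": "MOB", "name": "Medium grain organic","category": "whole", "grain_length": "medium", "n": 274,
     "mean": {"FD": 1.71, "Cir": 0.78, "AR": 2.33, "Ext": 0.67, "APIdx": 0.49, "L": 58.01, "a": 1.99,  "b": 1.08,  "YI": 2.67},
     "sd":   {"FD": 0.17, "Cir": 0.06, "AR": 0.31, "Ext": 0.10, "APIdx": 0.11, "L": 0.97,  "a": 0.20,  "b": 0.63,  "YI": 1.57}},
    {"class_id": 13, "abbreviation": "DGR", "name": "Doongara",            "category": "whole", "grain_length": "long",   "n": 308,
     "mean": {"FD": 1.59, "Cir": 0.67, "AR": 3.06, "Ext": 0.60, "APIdx": 0.63, "L": 52.99, "a": 1.51,  "b": 4.86,  "YI": 13.18},
     "sd":   {"FD": 0.09, "Cir": 0.03, "AR": 0.23, "Ext": 0.12, "APIdx": 0.09, "L": 1.65,  "a": 0.29,  "b": 1.81,  "YI": 5.09}},
    {"class_id": 14, "abbreviation": "BKR", "name": "Black rice",          "category": "whole", "grain_length": "long",   "n": 317,
     "mean": {"FD": 1.59, "Cir": 0.60, "AR": 3.56, "Ext": 0.56, "APIdx": 0.50, "L": 27.54, "a": 14.64, "b": 4.97,  "YI": 25.11},
     "sd":   {"FD": 0.09, "Cir": 0.05, "AR": 0.39, "Ext": 0.14, "APIdx": 0.11, "L": 2.22,  "a": 1.32,  "b": 2.35,  "YI": 10.43}},
    {"class_id": 15, "abbreviation": "WRO", "name": "Wild rice organic",   "category": "whole", "grain_length": "long",   "n": 335,
     "mean": {"FD": 1.66, "Cir": 0.46, "AR": 5.19, "Ext": 0.45, "APIdx": 0.39, "L": 29.60, "a": 7.95,  "b": 4.19,  "YI": 19.59},
     "sd":   {"FD": 0.12, "Cir": 0.05, "AR": 0.82, "Ext": 0.16, "APIdx": 0.12, "L": 2.32,  "a": 0.94,  "b": 2.88,  "YI": 13.50}}
  ],
  "model_stages": {
    "model_1": {"n_hidden": 7,
      "training": {"n": 2687, "accuracy": 95.0, "error": 5.0},
      "testing":  {"n": 1152, "accuracy": 87.8, "error": 12.2, "mse": 0.01},
      "overall":  {"n": 3839, "accuracy": 92.9, "error": 7.1}},
    "model_2": {"n_hidden": 10,
      "training": {"n": 6887, "accuracy": 91.6, "error": 8.4},
      "testing":  {"n": 2952, "accuracy": 88.5, "error": 11.5, "mse": 0.01},
      "overall":  {"n": 9839, "accuracy": 90.7, "error": 9.3}}
  },
  "second_lightbox": {"n_images_per_class": 8, "grains_per_image": 50, "n_classes": 15},
  "deployment_accuracy": {
    "KHO": 96.0, "SRS": 94.2, "BMB": 96.0, "CLP": 82.0, "ARB": 94.0,
    "CLS": 94.0, "LGW": 87.8, "JAS": 98.0, "BAS": 88.0, "BDM": 94.0,
    "MGB": 98.0, "MOB": 92.0, "DGR": 96.0, "BKR": 98.0, "WRO": 100.0,
    "mean": 93.9
  }
}
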