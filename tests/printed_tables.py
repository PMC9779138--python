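"""Published per-sub-range MAE/RMSE columns with their stated overall values.

These serve as fixtures for the aggregation identity: the overall value of a
group of equal-size sub-range models is the arithmetic mean of the per-sub-
range errors.  Each entry is (sub_range_values, stated_overall).  The NO
tables are omitted: two of them are an exact duplicate of each other in the
source (a publication artifact) and one contains non-estimable rows.
"""

# table id -> {k: {"mae": (values, overall), "rmse": (values, overall)}}
PRINTED_TABLES = {
    "pvs_o3_urban": {
        1: {"mae": ((8.4,), 8.4), "rmse": ((11.3,), 11.3)},
        2: {"mae": ((6.1, 10.4), 8.25), "rmse": ((8.5, 13.4), 10.94)},
        4: {"mae": ((3.5, 8.45, 9.84, 10.3), 8.02),
            "rmse": ((5.0, 10.8, 12.7, 13.2), 10.43)},
        8: {"mae": ((1.98, 4.81, 7.47, 9.4, 9.91, 9.98, 9.78, 10.81), 8.02),
            "rmse": ((2.8, 6.3, 9.6, 11.9, 12.7, 12.9, 12.7, 13.7), 10.34)},
    },
    "pvs_o3_rural": {
        1: {"mae": ((8.41,), 8.41), "rmse": ((10.7,), 10.7)},
        2: {"mae": ((7.66, 8.16), 7.91), "rmse": ((9.9, 10.3), 10.09)},
        4: {"mae": ((6.22, 8.52, 7.81, 7.64), 7.55),
            "rmse": ((8.2, 10.9, 10.0, 9.6), 9.68)},
        8: {"mae": ((5.46, 8.26, 8.57, 8.69, 7.86, 7.57, 7.60, 7.36), 7.67),
            "rmse": ((7.2, 10.6, 10.9, 11.3, 10.1, 9.6, 9.7, 9.3), 9.84)},
    },
    "rvs_o3_urban": {
        1: {"mae": ((8.4,), 8.4), "rmse": ((11.3,), 11.3)},
        2: {"mae": ((4.8, 8.8), 6.8), "rmse": ((6.3, 11.4), 8.9)},
        4: {"mae": ((2.2, 4.6, 5.1, 8.6), 5.1),
            "rmse": ((2.8, 5.6, 6.1, 11.1), 6.4)},
        8: {"mae": ((1.0, 1.8, 2.6, 2.8, 2.8, 3.1, 4.2, 8.3), 3.3),
            "rmse": ((1.2, 2.2, 3.0, 3.2, 3.3, 3.6, 5.1, 10.8), 4.0)},
    },
    "rvs_o3_rural": {
        1: {"mae": ((8.38,), 8.38), "rmse": ((10.7,), 10.7)},
        2: {"mae": ((5.97, 7.05), 6.51), "rmse": ((7.6, 8.9), 8.25)},
        4: {"mae": ((4.06, 3.85, 4.20, 6.56), 4.67),
            "rmse": ((5.1, 4.7, 5.1, 8.4), 5.84)},
        8: {"mae": ((2.98, 2.48, 2.27, 2.17, 2.28, 2.56, 3.68, 6.06), 3.06),
            "rmse": ((3.6, 3.0, 2.7, 2.6, 2.6, 3.1, 4.5, 7.9), 3.74)},
    },
    "pvs_no2_urban": {
        1: {"mae": ((5.3,), 5.3), "rmse": ((7.4,), 7.4)},
        2: {"mae": ((3.13, 7.29), 5.21), "rmse": ((4.2, 9.6), 6.89)},
        4: {"mae": ((2.29, 3.85, 5.89, 8.54), 5.14),
            "rmse": ((3.0, 5.0, 7.6, 11.1), 6.66)},
        8: {"mae": ((1.80, 2.88, 3.43, 4.33, 5.71, 6.33, 7.65, 9.47), 5.20),
            "rmse": ((2.4, 3.7, 4.4, 5.6, 7.3, 8.2, 9.9, 12.3), 6.72)},
    },
    "pvs_no2_rural": {
        1: {"mae": ((1.919,), 1.919), "rmse": ((2.65,), 2.65)},
        2: {"mae": ((1.268, 2.435), 1.852), "rmse": ((1.69, 3.24), 2.463)},
        4: {"mae": ((0.989, 0.989, 1.852, 2.915), 1.686),
            "rmse": ((1.33, 1.33, 2.39, 3.78), 2.207)},
        8: {"mae": ((0.812, 1.273, 1.366, 1.671, 1.786, 1.972, 2.361, 3.246), 1.811),
            "rmse": ((1.08, 1.66, 1.73, 2.17, 2.26, 2.55, 3.06, 4.22), 2.342)},
    },
    "rvs_no2_urban": {
        1: {"mae": ((5.31,), 5.31), "rmse": ((7.49,), 7.49)},
        2: {"mae": ((2.37, 6.47), 4.42), "rmse": ((2.97, 8.84), 5.91)},
        4: {"mae": ((1.56, 1.82, 2.73, 6.61), 3.18),
            "rmse": ((1.91, 2.19, 3.27, 9.03), 4.10)},
        8: {"mae": ((1.03, 0.86, 0.93, 1.12, 1.40, 1.68, 2.44, 6.84), 2.04),
            "rmse": ((1.26, 1.00, 1.07, 1.32, 1.64, 1.97, 2.87, 9.44), 2.57)},
    },
    "rvs_no2_rural": {
        1: {"mae": ((1.919,), 1.919), "rmse": ((2.672,), 2.672)},
        2: {"mae": ((0.894, 2.164), 1.529), "rmse": ((1.110, 2.985), 2.047)},
        4: {"mae": ((0.593, 0.586, 0.891, 2.529), 1.150),
            "rmse": ((0.726, 0.706, 1.088, 3.426), 1.487)},
        8: {"mae": ((0.427, 0.304, 0.283, 0.332, 0.438, 0.631, 1.107, 2.661), 0.773),
            "rmse": ((0.521, 0.354, 0.349, 0.408, 0.501, 0.736, 1.332, 3.544), 0.968)},
    },
    "pvs_so2_urban": {
        1: {"mae": ((5.25,), 5.25), "rmse": ((8.1,), 8.1)},
        2: {"mae": ((2.57, 7.78), 5.17), "rmse": ((3.7, 10.9), 7.30)},
        4: {"mae": ((1.81, 3.30, 5.88, 9.69), 5.17),
            "rmse": ((2.6, 4.6, 8.1, 13.3), 7.15)},
        8: {"mae": ((1.49, 2.19, 2.85, 3.85, 5.46, 6.69, 7.08, 11.82), 5.18),
            "rmse": ((2.2, 3.0, 3.9, 5.3, 7.5, 9.1, 9.3, 15.9), 7.02)},
    },
    "pvs_so2_rural": {
        1: {"mae": ((1.920,), 1.920), "rmse": ((3.133,), 3.133)},
        2: {"mae": ((0.935, 2.899), 1.917), "rmse": ((1.302, 4.298), 2.800)},
        4: {"mae": ((0.823, 1.135, 1.710, 3.836), 1.876),
            "rmse": ((1.099, 1.597, 2.395, 5.389), 2.620)},
        8: {"mae": ((0.699, 0.855, 1.008, 1.246, 0.057, 2.024, 3.108, 5.072), 1.759),
            "rmse": ((0.899, 1.131, 1.379, 1.778, 0.080, 2.813, 4.545, 6.681), 2.413)},
    },
    "rvs_so2_urban": {
        1: {"mae": ((5.26,), 5.26), "rmse": ((8.15,), 8.15)},
        2: {"mae": ((1.58, 7.08), 4.33), "rmse": ((1.95, 10.33), 6.14)},
        4: {"mae": ((0.85, 1.11, 2.66, 8.11), 3.18),
            "rmse": ((1.03, 1.32, 3.21, 11.64), 4.30)},
        8: {"mae": ((0.55, 0.41, 0.48, 0.73, 1.16, 1.82, 3.02, 9.84), 2.25),
            "rmse": ((0.64, 0.48, 0.56, 0.85, 1.36, 2.14, 3.58, 14.21), 2.98)},
    },
    "rvs_so2_rural": {
        1: {"mae": ((1.96,), 1.96), "rmse": ((3.186,), 3.186)},
        2: {"mae": ((0.63, 2.68), 1.66), "rmse": ((0.780, 4.116), 2.45)},
        4: {"mae": ((0.38, 0.36, 0.73, 3.45), 1.23),
            "rmse": ((0.455, 0.461, 0.891, 5.048), 1.71)},
        8: {"mae": ((0.26, 0.04, 0.19, 0.23, 0.34, 0.58, 1.01, 4.05), 0.84),
            "rmse": ((0.333, 0.063, 0.245, 0.289, 0.385, 0.683, 1.216, 5.909), 1.14)},
    },
    "pvs_pm10_urban": {
        1: {"mae": ((11.83,), 11.83), "rmse": ((18.7,), 18.7)},
        2: {"mae": ((6.53, 16.99), 11.76), "rmse": ((8.79, 25.22), 17.00)},
        4: {"mae": ((5.52, 7.42, 10.01, 23.07), 11.51),
            "rmse": ((7.6, 9.7, 13.2, 32.6), 15.76)},
        8: {"mae": ((4.47, 6.39, 6.72, 8.24, 9.18, 11.11, 14.67, 28.79), 11.20),
            "rmse": ((5.9, 8.8, 8.9, 10.7, 12.1, 14.4, 19.0, 39.7), 14.93)},
    },
    "pvs_pm10_rural": {
        1: {"mae": ((6.726,), 6.726), "rmse": ((9.10,), 9.10)},
        2: {"mae": ((4.638, 8.541), 6.589), "rmse": ((6.11, 11.18), 8.646)},
        4: {"mae": ((3.964, 5.230, 6.602, 9.972), 6.442),
            "rmse": ((5.12, 6.76, 8.57, 12.70), 8.285)},
        8: {"mae": ((3.406, 4.634, 4.963, 5.613, 6.751, 7.202, 8.027, 12.516), 6.639),
            "rmse": ((4.39, 6.01, 6.43, 7.20, 8.74, 9.28, 10.23, 15.88), 8.519)},
    },
    "rvs_pm10_urban": {
        1: {"mae": ((11.84,), 11.84), "rmse": ((18.8,), 18.8)},
        2: {"mae": ((4.66, 15.20), 9.93), "rmse": ((5.8, 23.8), 14.77)},
        4: {"mae": ((3.09, 2.97, 5.02, 20.23), 7.83),
            "rmse": ((3.8, 3.5, 6.1, 30.4), 10.96)},
        8: {"mae": ((2.26, 1.49, 1.51, 1.74, 2.30, 3.51, 6.99, 26.32), 5.76),
            "rmse": ((2.8, 1.7, 1.8, 2.0, 2.7, 4.1, 8.4, 38.0), 7.68)},
    },
    "rvs_pm10_rural": {
        1: {"mae": ((6.88,), 6.88), "rmse": ((9.34,), 9.34)},
        2: {"mae": ((2.99, 7.11), 5.05), "rmse": ((3.64, 9.75), 6.70)},
        4: {"mae": ((1.88, 1.62, 2.29, 8.07), 3.46),
            "rmse": ((2.31, 1.90, 2.71, 11.00), 4.48)},
        8: {"mae": ((1.43, 0.84, 0.84, 0.89, 1.04, 1.46, 2.50, 7.88), 2.11),
            "rmse": ((1.76, 0.99, 0.97, 1.03, 1.21, 1.69, 2.94, 10.71), 2.66)},
    },
    "pvs_co_urban": {
        1: {"mae": ((0.119,), 0.119), "rmse": ((0.202,), 0.202)},
        2: {"mae": ((0.071, 0.162), 0.117), "rmse": ((0.155, 0.230), 0.193)},
        4: {"mae": ((0.066, 0.074, 0.111, 0.210), 0.115),
            "rmse": ((0.196, 0.098, 0.149, 0.285), 0.182)},
        8: {"mae": ((0.072, 0.069, 0.065, 0.079, 0.099, 0.121, 0.153, 0.275), 0.117),
            "rmse": ((0.198, 0.177, 0.085, 0.106, 0.132, 0.158, 0.203, 0.365), 0.178)},
    },
    "rvs_co_urban": {
        1: {"mae": ((0.118,), 0.118), "rmse": ((0.198,), 0.198)},
        2: {"mae": ((0.047, 0.160), 0.104), "rmse": ((0.059, 0.262), 0.161)},
        4: {"mae": ((0.034, 0.030, 0.055, 0.196), 0.078),
            "rmse": ((0.042, 0.035, 0.066, 0.274), 0.104)},
        8: {"mae": ((0.027, 0.014, 0.014, 0.018, 0.025, 0.038, 0.077, 0.223), 0.055),
            "rmse": ((0.033, 0.016, 0.017, 0.021, 0.030, 0.045, 0.093, 0.309), 0.070)},
    },
}


def decimals(x: float) -> int:
    s = repr(float(x))
    return len(s.split(".")[1]) if "." in s else 0
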