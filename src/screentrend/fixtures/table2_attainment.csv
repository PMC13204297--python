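unit,sex,apc_mean,apc_lo,apc_hi,prob_target,prob_target_lo,prob_target_hi,target_year,on_track_flag
nationwide,total,0.83,-0.05,1.67,0.113,0.063,0.163,2040,0
nationwide,men,0.64,-0.35,1.55,0.254,0.204,0.304,2040,0
nationwide,women,1.01,0.11,1.93,0.070,0.020,0.120,2039,0
Hokkaido,total,0.55,-0.42,1.46,0.016,,,2080,0
Hokkaido,men,0.52,-0.65,1.63,0.050,,,2075,0
Hokkaido,women,0.56,-0.39,1.48,0.012,,,2086,0
Aomori,total,1.23,-0.42,2.76,0.802,,,2028,1
Aomori,men,0.96,-0.96,2.84,0.790,,,2029,1
Aomori,women,1.34,0.17,2.36,0.794,,,2029,1
Iwate,total,0.71,-0.22,1.60,0.877,,,2026,1
Iwate,men,0.64,-1.34,2.69,0.782,,,2032,0
Iwate,women,0.78,0.01,1.57,0.840,,,2028,1
Miyagi,total,0.59,-0.81,2.01,0.846,,,2024,1
Miyagi,men,0.32,-0.91,1.60,0.888,,,2015,1
Miyagi,women,0.70,-1.13,2.45,0.707,,,2036,0
Akita,total,0.57,-0.75,1.89,0.521,,,2042,0
Akita,men,0.55,-0.87,1.93,0.744,,,2033,0
Akita,women,0.75,-0.64,2.15,0.455,,,2039,0
Yamagata,total,0.99,0.09,1.88,0.991,,,2014,1
Yamagata,men,0.82,-0.37,2.08,0.981,,,2013,1
Yamagata,women,1.18,-0.05,2.47,0.981,,,2016,1
Fukushima,total,0.64,-0.38,1.66,0.564,,,2034,0
Fukushima,men,0.45,-0.19,1.07,0.843,,,2027,1
Fukushima,women,0.76,-0.79,2.22,0.346,,,2044,0
Ibaraki,total,0.64,-1.24,2.53,0.267,,,2091,0
Ibaraki,men,0.48,-1.54,2.50,0.365,,,never,0
Ibaraki,women,0.77,-1.20,2.54,0.197,,,2063,0
Tochigi,total,0.55,-0.86,1.98,0.273,,,2064,0
Tochigi,men,0.37,-0.96,1.68,0.346,,,never,0
Tochigi,women,0.66,-0.74,1.98,0.178,,,2053,0
Gunma,total,0.84,-0.92,2.54,0.694,,,2033,0
Gunma,men,0.70,-1.12,2.60,0.728,,,2037,0
Gunma,women,0.95,-0.93,2.63,0.595,,,2035,0
Saitama,total,0.68,-0.66,1.95,0.071,,,2060,0
Saitama,men,0.33,-1.00,1.55,0.069,,,never,0
Saitama,women,1.02,-0.23,2.13,0.071,,,2044,0
Chiba,total,0.75,-0.24,1.76,0.214,,,2039,0
Chiba,men,0.58,-0.26,1.39,0.292,,,2038,0
Chiba,women,0.92,-0.11,1.95,0.170,,,2038,0
Tokyo,total,1.16,-0.02,2.28,0.377,,,2034,0
Tokyo,men,0.78,-0.49,1.93,0.381,,,2037,0
Tokyo,women,1.48,0.21,2.56,0.407,,,2032,0
Kanagawa,total,0.87,0.14,1.54,0.072,,,2037,0
Kanagawa,men,0.56,-0.29,1.33,0.235,,,2039,0
Kanagawa,women,1.16,0.49,1.79,0.039,,,2036,0
Niigata,total,0.62,-0.86,2.12,0.850,,,2024,1
Niigata,men,0.43,-1.20,2.20,0.852,,,2016,1
Niigata,women,0.77,-0.44,1.92,0.810,,,2028,1
Toyama,total,0.80,0.12,1.49,0.903,,,2026,1
Toyama,men,0.51,-0.32,1.38,0.880,,,2025,1
Toyama,women,1.03,0.22,1.82,0.879,,,2027,1
Ishikawa,total,0.81,-0.64,2.18,0.597,,,2035,0
Ishikawa,men,0.71,-1.41,2.81,0.737,,,2038,0
Ishikawa,women,0.88,-0.22,1.87,0.240,,,2037,0
Fukui,total,0.43,-0.24,1.08,0.041,,,2055,0
Fukui,men,0.24,-0.48,0.96,0.075,,,never,0
Fukui,women,0.73,0.07,1.43,0.051,,,2041,0
Yamanashi,total,0.94,0.20,1.70,0.980,,,2019,1
Yamanashi,men,0.67,-0.34,1.76,0.959,,,2017,1
Yamanashi,women,1.15,0.27,2.06,0.970,,,2022,1
Nagano,total,0.72,-0.08,1.50,0.737,,,2030,1
Nagano,men,0.66,-0.38,1.73,0.885,,,2024,1
Nagano,women,0.82,-0.06,1.66,0.345,,,2034,0
Gifu,total,1.24,0.07,2.30,0.593,,,2031,0
Gifu,men,1.33,0.07,2.56,0.916,,,2025,1
Gifu,women,1.22,0.25,2.14,0.143,,,2035,0
Shizuoka,total,0.61,-0.37,1.57,0.272,,,2040,0
Shizuoka,men,0.48,-0.40,1.42,0.502,,,2038,0
Shizuoka,women,0.71,-0.46,1.85,0.168,,,2045,0
Aichi,total,0.84,-0.18,1.78,0.094,,,2042,0
Aichi,men,0.63,-0.11,1.37,0.110,,,2041,0
Aichi,women,1.04,-0.23,2.16,0.090,,,2042,0
Mie,total,0.91,-0.35,2.10,0.167,,,2041,0
Mie,men,0.67,-0.33,1.61,0.195,,,2041,0
Mie,women,1.08,-0.49,2.43,0.150,,,2042,0
Shiga,total,0.87,-0.72,2.32,0.184,,,2048,0
Shiga,men,0.64,-1.13,2.33,0.377,,,2058,0
Shiga,women,1.12,-0.29,2.33,0.111,,,2042,0
Kyoto,total,0.49,-0.80,1.72,0.032,,,never,0
Kyoto,men,0.33,-1.60,2.17,0.095,,,never,0
Kyoto,women,0.60,-0.37,1.42,0.011,,,2073,0
Osaka,total,1.10,-0.01,2.10,0.057,,,2042,0
Osaka,men,1.03,-0.01,1.96,0.091,,,2039,0
Osaka,women,1.12,-0.19,2.13,0.045,,,2044,0
Hyogo,total,0.82,-0.24,1.90,0.049,,,2050,0
Hyogo,men,0.42,-1.25,1.97,0.104,,,never,0
Hyogo,women,1.11,0.41,1.80,0.021,,,2040,0
Nara,total,1.00,-0.42,2.22,0.090,,,2045,0
Nara,men,1.06,0.12,2.00,0.367,,,2033,0
Nara,women,0.90,-0.82,2.25,0.054,,,2058,0
Wakayama,total,0.64,-0.28,1.46,0.028,,,2055,0
Wakayama,men,0.46,-0.22,1.10,0.022,,,2062,0
Wakayama,women,0.84,-0.04,1.63,0.024,,,2048,0
Tottori,total,0.86,0.07,1.70,0.799,,,2029,1
Tottori,men,0.76,-0.83,2.30,0.806,,,2028,1
Tottori,women,0.99,0.18,1.78,0.688,,,2030,1
Shimane,total,0.91,-0.69,2.50,0.719,,,2032,0
Shimane,men,0.68,-1.69,2.97,0.688,,,2062,0
Shimane,women,1.09,-0.26,2.32,0.678,,,2031,0
Okayama,total,0.63,0.00,1.26,0.696,,,2030,1
Okayama,men,0.59,-0.02,1.28,0.874,,,2027,1
Okayama,women,0.70,0.04,1.34,0.481,,,2032,0
Hiroshima,total,0.75,0.03,1.42,0.027,,,2045,0
Hiroshima,men,0.91,-0.02,1.84,0.368,,,2034,0
Hiroshima,women,0.54,-0.22,1.23,0.009,,,2071,0
Yamaguchi,total,0.48,-0.13,1.12,0.011,,,2068,0
Yamaguchi,men,0.44,-0.33,1.18,0.048,,,2058,0
Yamaguchi,women,0.41,-0.27,1.06,0.005,,,never,0
Tokushima,total,0.82,-0.13,1.66,0.043,,,2045,0
Tokushima,men,0.89,-0.56,2.23,0.219,,,2043,0
Tokushima,women,0.83,0.02,1.57,0.020,,,2047,0
Kagawa,total,0.76,-1.66,3.04,0.543,,,2064,0
Kagawa,men,0.56,-1.76,3.09,0.610,,,never,0
Kagawa,women,0.83,-1.45,2.91,0.393,,,2058,0
Ehime,total,0.58,-0.14,1.28,0.028,,,2051,0
Ehime,men,0.71,-0.70,2.04,0.383,,,2042,0
Ehime,women,0.46,-0.53,1.38,0.018,,,2089,0
Kochi,total,1.09,-0.13,2.24,0.841,,,2028,1
Kochi,men,1.13,-0.01,2.21,0.916,,,2025,1
Kochi,women,1.19,-0.28,2.57,0.811,,,2028,1
Fukuoka,total,0.89,-0.32,1.96,0.060,,,2047,0
Fukuoka,men,0.79,-0.37,1.85,0.115,,,2044,0
Fukuoka,women,0.95,-0.24,1.98,0.040,,,2049,0
Saga,total,1.01,0.40,1.62,0.490,,,2031,0
Saga,men,0.96,-0.45,2.43,0.709,,,2031,0
Saga,women,0.88,0.18,1.57,0.087,,,2036,0
Nagasaki,total,0.83,0.29,1.36,0.013,,,2044,0
Nagasaki,men,0.48,-0.09,1.04,0.011,,,2062,0
Nagasaki,women,1.10,0.16,1.92,0.042,,,2041,0
Kumamoto,total,0.67,-2.67,3.69,0.386,,,never,0
Kumamoto,men,0.62,-2.97,3.95,0.529,,,never,0
Kumamoto,women,0.70,-1.57,2.63,0.169,,,never,0
Oita,total,0.85,-1.21,2.74,0.343,,,2054,0
Oita,men,0.67,-1.41,2.71,0.483,,,2069,0
Oita,women,1.04,-0.88,2.79,0.301,,,2044,0
Miyazaki,total,0.88,-0.28,1.99,0.203,,,2039,0
Miyazaki,men,0.91,-0.01,1.75,0.595,,,2031,0
Miyazaki,women,0.97,-0.19,2.06,0.132,,,2040,0
Kagoshima,total,0.50,-1.67,2.69,0.319,,,never,0
Kagoshima,men,0.49,-1.53,2.54,0.436,,,never,0
Kagoshima,women,0.47,-2.29,3.08,0.265,,,never,0
Okinawa,total,0.36,-0.41,1.10,0.011,,,never,0
Okinawa,men,0.21,-0.70,1.07,0.014,,,never,0
Okinawa,women,0.54,-0.10,1.18,0.010,,,2064,0
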