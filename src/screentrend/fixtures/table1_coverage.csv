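unit,sex,coverage_2013_pct,coverage_2022_pct,proj2028_mean_pct,proj2028_lo_pct,proj2028_hi_pct
nationwide,total,42.3,49.7,55.8,44.5,66.3
nationwide,men,47.5,53.2,58.0,47.4,68.3
nationwide,women,37.4,46.4,53.8,42.5,64.9
Hokkaido,total,35.7,40.7,45.4,34.0,57.0
Hokkaido,men,42.1,47.1,51.6,39.1,64.6
Hokkaido,women,30.0,34.9,40.0,29.4,51.3
Aomori,total,44.7,55.3,64.0,47.5,79.4
Aomori,men,49.0,57.0,64.0,43.6,80.9
Aomori,women,41.6,53.6,62.7,50.7,73.7
Iwate,total,52.3,59.0,63.3,53.7,71.9
Iwate,men,53.3,59.5,64.4,43.2,82.2
Iwate,women,51.3,58.6,62.4,54.3,70.1
Miyagi,total,55.1,60.0,64.4,48.0,78.2
Miyagi,men,59.9,62.4,65.3,51.5,77.4
Miyagi,women,50.7,56.8,62.4,42.0,79.0
Akita,total,50.9,55.4,59.9,45.4,72.7
Akita,men,54.0,58.1,62.6,46.4,76.7
Akita,women,47.9,53.7,59.3,43.5,72.7
Yamagata,total,60.0,69.0,74.1,65.2,81.4
Yamagata,men,62.5,69.8,74.5,62.8,83.9
Yamagata,women,56.6,67.6,73.4,61.3,83.2
Fukushima,total,50.8,55.8,60.4,49.8,70.7
Fukushima,men,55.1,59.1,62.0,55.6,68.2
Fukushima,women,46.2,52.0,58.1,41.5,74.7
Ibaraki,total,44.2,50.3,56.1,36.0,76.1
Ibaraki,men,48.3,53.2,57.5,35.0,77.0
Ibaraki,women,40.0,47.3,54.1,32.2,75.0
Tochigi,total,47.7,52.4,57.1,40.1,72.7
Tochigi,men,51.7,54.7,58.2,43.2,72.1
Tochigi,women,44.2,50.1,55.6,39.7,70.7
Gunma,total,48.8,55.7,62.2,42.7,79.0
Gunma,men,51.3,57.4,63.2,41.1,82.4
Gunma,women,46.0,53.6,60.8,42.2,76.8
Saitama,total,40.2,45.9,51.6,36.4,66.1
Saitama,men,46.2,48.6,52.2,37.9,66.9
Saitama,women,34.3,43.4,51.6,36.9,66.1
Chiba,total,45.2,52.2,57.4,47.3,67.3
Chiba,men,49.2,54.6,58.5,49.4,67.1
Chiba,women,41.4,50.1,56.4,44.1,67.8
Tokyo,total,40.7,50.5,58.7,44.3,72.1
Tokyo,men,46.4,53.0,58.8,45.5,70.8
Tokyo,women,35.2,48.3,58.9,44.4,71.9
Kanagawa,total,41.8,50.0,55.7,47.7,63.8
Kanagawa,men,49.2,54.9,58.1,48.7,66.3
Kanagawa,women,34.6,45.4,53.6,44.8,62.5
Niigata,total,54.5,60.6,64.7,48.4,78.7
Niigata,men,58.3,62.7,65.9,46.8,81.6
Niigata,women,50.7,58.1,63.3,50.2,75.0
Toyama,total,51.2,58.1,63.2,56.1,69.7
Toyama,men,55.7,59.7,63.0,53.5,71.5
Toyama,women,47.6,57.4,63.1,54.8,70.9
Ishikawa,total,47.5,54.5,60.7,43.9,75.3
Ishikawa,men,51.8,57.6,63.4,40.7,82.0
Ishikawa,women,43.3,51.1,57.5,45.7,68.2
Fukui,total,47.9,51.5,54.5,47.6,61.1
Fukui,men,51.9,54.1,55.9,48.5,63.4
Fukui,women,43.8,50.0,54.7,47.0,62.2
Yamanashi,total,54.5,62.9,68.4,60.8,75.2
Yamanashi,men,57.6,63.6,67.6,57.3,77.4
Yamanashi,women,50.9,61.4,68.2,59.1,77.0
Nagano,total,50.2,57.1,61.3,53.2,68.9
Nagano,men,54.5,61.2,64.1,52.0,75.0
Nagano,women,45.8,53.3,58.8,49.2,67.9
Gifu,total,40.9,51.9,60.6,47.7,72.3
Gifu,men,46.3,57.6,66.2,53.2,77.8
Gifu,women,35.8,46.9,55.9,43.6,67.5
Shizuoka,total,48.1,54.4,58.1,47.0,68.5
Shizuoka,men,52.1,56.8,59.8,49.6,68.9
Shizuoka,women,44.3,51.8,56.1,42.2,68.7
Aichi,total,40.9,48.5,54.7,43.1,65.8
Aichi,men,46.7,52.3,56.7,48.6,64.5
Aichi,women,35.2,44.9,53.1,38.8,66.7
Mie,total,40.4,48.7,55.6,41.8,69.3
Mie,men,46.6,52.4,57.2,46.7,67.1
Mie,women,34.5,45.1,53.8,34.8,72.0
Shiga,total,39.6,47.6,55.0,37.8,72.0
Shiga,men,46.9,52.7,58.1,38.6,75.7
Shiga,women,33.1,43.6,52.8,35.6,69.7
Kyoto,total,37.8,42.0,46.9,33.0,61.8
Kyoto,men,43.5,45.5,49.8,28.7,70.7
Kyoto,women,32.8,38.6,43.6,32.8,54.6
Osaka,total,32.3,42.2,51.2,38.1,64.6
Osaka,men,37.4,46.6,54.4,42.4,66.3
Osaka,women,27.9,38.4,48.7,33.0,65.5
Hyogo,total,37.0,44.2,50.7,38.9,62.2
Hyogo,men,44.8,48.0,52.4,35.6,68.9
Hyogo,women,30.1,40.7,49.3,40.0,58.6
Nara,total,35.5,44.0,52.1,35.3,67.9
Nara,men,43.2,52.0,58.9,47.7,69.1
Nara,women,29.7,37.6,46.2,27.9,65.0
Wakayama,total,40.0,46.5,50.7,40.3,61.0
Wakayama,men,44.7,48.9,52.3,44.1,60.3
Wakayama,women,35.9,44.6,49.9,39.0,61.1
Tottori,total,48.7,56.3,62.0,53.6,70.1
Tottori,men,51.4,58.5,63.8,47.7,77.8
Tottori,women,45.8,55.4,61.0,52.3,69.0
Shimane,total,47.8,55.8,62.6,45.0,78.9
Shimane,men,51.1,56.6,62.5,35.9,83.0
Shimane,women,43.8,53.8,61.5,47.4,73.6
Okayama,total,52.1,57.7,60.8,54.0,67.3
Okayama,men,54.2,59.1,62.3,55.6,68.8
Okayama,women,49.7,56.3,59.9,53.1,66.6
Hiroshima,total,41.3,47.7,52.3,43.7,60.6
Hiroshima,men,46.3,54.3,59.0,48.6,68.5
Hiroshima,women,36.9,41.5,45.7,36.9,55.3
Yamaguchi,total,40.9,45.5,48.8,41.8,56.3
Yamaguchi,men,47.1,51.6,54.4,46.4,62.2
Yamaguchi,women,35.2,39.0,42.3,34.9,49.8
Tokushima,total,39.5,46.4,52.3,40.8,63.8
Tokushima,men,43.6,50.7,56.4,41.2,70.8
Tokushima,women,36.1,43.3,49.4,39.7,59.3
Kagawa,total,46.3,54.0,60.3,35.9,81.3
Kagawa,men,51.1,56.9,61.2,31.2,85.1
Kagawa,women,42.6,50.5,57.7,32.6,79.6
Ehime,total,43.4,48.4,52.6,45.0,60.1
Ehime,men,46.9,53.1,58.7,42.8,73.3
Ehime,women,40.1,43.7,47.1,36.5,58.0
Kochi,total,46.5,56.5,63.7,50.0,76.4
Kochi,men,47.9,58.7,65.6,54.6,75.4
Kochi,women,44.6,56.1,63.9,48.6,77.6
Fukuoka,total,36.2,44.4,51.6,38.1,65.3
Fukuoka,men,41.6,48.8,54.8,42.4,66.6
Fukuoka,women,31.5,40.4,48.4,33.6,63.4
Saga,total,45.3,54.4,59.8,52.8,66.2
Saga,men,49.7,58.4,62.1,45.5,77.1
Saga,women,42.2,50.6,56.3,48.7,63.9
Nagasaki,total,37.3,44.9,50.5,43.9,57.1
Nagasaki,men,43.0,47.4,50.0,43.7,56.5
Nagasaki,women,32.3,42.6,51.2,39.3,62.6
Kumamoto,total,47.1,52.8,57.5,14.9,90.6
Kumamoto,men,49.6,54.7,59.3,7.1,96.5
Kumamoto,women,44.9,51.1,55.7,28.9,79.7
Oita,total,41.8,49.8,57.1,33.7,78.2
Oita,men,47.2,53.4,59.3,35.9,79.9
Oita,women,37.8,47.8,56.3,32.9,77.1
Miyazaki,total,42.1,50.4,56.7,43.7,69.2
Miyazaki,men,46.1,54.5,60.5,50.9,69.6
Miyazaki,women,38.5,48.0,55.0,40.5,68.5
Kagoshima,total,46.4,51.4,56.4,31.5,78.9
Kagoshima,men,49.2,54.4,58.6,34.9,78.7
Kagoshima,women,43.1,48.0,53.7,22.5,82.3
Okinawa,total,40.8,44.5,47.2,39.0,55.6
Okinawa,men,42.9,44.9,47.1,36.8,57.5
Okinawa,women,38.9,44.3,47.7,40.5,54.8
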