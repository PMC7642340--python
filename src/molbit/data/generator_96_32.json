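{
 "n": 96,
 "k": 32,
 "seed": 20201103,
 "verified_weight_floor": 19,
 "search_iters": 100000,
 "rows_hex": [
  "600701725bf33601a9b1e6f4",
  "0cdce0338f14025a0a281fdf",
  "1056f3b5721c6ed48f62e5e6",
  "59cbd5f0b11af1563b436669",
  "cf3d882425d41c955f157b64",
  "c64dc0ea6c0ff4c773f0b8e8",
  "589b524d66763ce3984a2a97",
  "4cc37a0e72a7300962c2dc6e",
  "8fb981f688e87f811fa7e48d",
  "843affbd62af5d03363c8c4c",
  "0781427ee8ed803aa431e20c",
  "4433f2083a80947b219ade21",
  "2c2bd7894a5b2538df0d845a",
  "cd92b4534a53efdf181533a3",
  "3a4a696803a4e1389beb5c46",
  "28c43241300d1dae5d996cb4",
  "65a9a256990113d0ccef3287",
  "73b03977dd2336260d0470a9",
  "64e8bc29d560863c93c51c59",
  "4e1049f8fb0bd28a04986937",
  "dc7ff297d1fa8fb9506acc2f",
  "9e41f0a7620ca86270f5f8bd",
  "d5d57d60b29a35d7418b4656",
  "d7ac1880d411826e63624ecf",
  "c08b14a680250239c28c96bf",
  "ee1f2f13ea72ef87aa5bac28",
  "971f8cd5ff8cb973acf2599e",
  "3c3497a051d72aaaa1f84492",
  "4526d1fe03e5afcf3b0eb147",
  "d1b2d7bbf47c020edf7fa83e",
  "0e3b86f723ac6cdf32c9ce0b",
  "d244155e1fd3cbba707675ec"
 ]
}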