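{
 "model_version": "ord2011-dutta2017-v1",
 "protocol": {
  "n_beats": 10000,
  "cl_ms": 2000.0,
  "cell_type": "endo"
 },
 "state": {
  "v": -87.88543844881838,
  "nai": 6.400359315741568,
  "nass": 6.400418100700607,
  "ki": 144.82272913780395,
  "kss": 144.82271253657856,
  "cai": 7.411509879319235e-05,
  "cass": 7.264651944161473e-05,
  "cansr": 1.3704428898956225,
  "cajsr": 1.3708517249468721,
  "m": 0.007430637222699074,
  "hf": 0.6940590701060614,
  "hs": 0.6940589525546106,
  "j": 0.6940582029059147,
  "hsp": 0.45027284971449255,
  "jp": 0.694057636615913,
  "mL": 0.00019247256655855624,
  "hL": 0.5090812223236679,
  "hLp": 0.303806677879444,
  "a": 0.0010089830645929568,
  "iF": 0.9995450533682352,
  "iS": 0.8688488025405368,
  "ap": 0.000514106096378533,
  "iFp": 0.9995450534224185,
  "iSp": 0.9024686888725822,
  "d": 2.406103466114917e-09,
  "ff": 0.999999990584489,
  "fs": 0.9693637161821536,
  "fcaf": 0.9999999905844894,
  "fcas": 0.9999999754104373,
  "jca": 0.9999999905175426,
  "nca": 0.0015069630926946335,
  "ffp": 0.9999999905844611,
  "fcafp": 0.9999999905844629,
  "xrf": 8.15192861406094e-06,
  "xrs": 0.16482222128255924,
  "xs1": 0.13822285453553104,
  "xs2": 0.00019531782987333,
  "xk1": 0.9967898494852699,
  "Jrelnp": 1.4572561885663513e-07,
  "Jrelp": 1.8215573655760491e-07,
  "CaMKt": 0.003220505221820131
 }
}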