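51083f63dd9df9b50f6c1b4c61b86c8deaa64b2c2767973cbb7a09dc06581eaf  synthetic_absorbance_L.csv
8b5209f48d68f8f92af1555bb6074938333db9f28765cc70f22205fd89d2476c  synthetic_absorbance_M.csv
514a49de7348aff9ee9fd7d4e4be7e5f692eb6971350edcd1de02dbdbeceb883  synthetic_absorbance_S.csv
408f6977adbab54c6da1d5ace073d5e246bfafbb74c55ed76f966b31c7750b96  synthetic_cie1964_10deg.csv
accd8ce6eaa623f9018f02996ba28cd40af8599f45760dd5ab5478c08214f52e  synthetic_docul1.csv
a42069e934d48bd02014743103d9e488cfec327a3328904a0f0ad76eddc207fd  synthetic_docul2.csv
2bce4bf2f50126fb5152b39f31e9761ab497a36e5332e807f10e68ed1c4d3535  synthetic_macula_relative.csv
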