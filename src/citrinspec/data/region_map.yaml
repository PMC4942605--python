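# Province/municipality -> region, relative to the Yangtze River boundary.
north:
  - Beijing
  - Inner Mongolia
  - Shandong
  - Shanxi
  - Shaanxi
  - Henan
  - Hebei
  - Liaoning
  - Jilin
  - Heilongjiang
border:
  - Shanghai
  - Jiangsu
  - Anhui
  - Hubei
  - Sichuan
  - Chongqing
south:
  - Guangdong
  - Guangxi
  - Yunnan
  - Guizhou
  - Hunan
  - Fujian
  - Zhejiang
  - Jiangxi
  - Hainan
  - Taiwan
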