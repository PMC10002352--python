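province,window,pollution_type,quadrant
Anhui,2011-2015,domestic,both_positive
Beijing,2011-2015,domestic,both_negative
Chongqing,2011-2015,domestic,pos_neg
Fujian,2011-2015,domestic,both_positive
Gansu,2011-2015,domestic,both_positive
Guangdong,2011-2015,domestic,both_positive
Guangxi,2011-2015,domestic,pos_neg
Guizhou,2011-2015,domestic,both_positive
Hainan,2011-2015,domestic,pos_neg
Hebei,2011-2015,domestic,both_positive
Heilongjiang,2011-2015,domestic,both_positive
Henan,2011-2015,domestic,pos_neg
Hubei,2011-2015,domestic,both_negative
Hunan,2011-2015,domestic,both_positive
Jiangsu,2011-2015,domestic,neg_pos
Jiangxi,2011-2015,domestic,both_positive
Jilin,2011-2015,domestic,pos_neg
Liaoning,2011-2015,domestic,both_positive
Nei Mongol,2011-2015,domestic,both_negative
Ningxia,2011-2015,domestic,both_positive
Qinghai,2011-2015,domestic,both_negative
Shaanxi,2011-2015,domestic,both_negative
Shandong,2011-2015,domestic,neg_pos
Shanghai,2011-2015,domestic,both_positive
Shanxi,2011-2015,domestic,both_positive
Sichuan,2011-2015,domestic,both_positive
Tianjin,2011-2015,domestic,both_positive
Xinjiang,2011-2015,domestic,pos_neg
Xizang,2011-2015,domestic,both_positive
Yunnan,2011-2015,domestic,both_positive
Zhejiang,2011-2015,domestic,both_positive
Anhui,2016-2020,domestic,pos_neg
Beijing,2016-2020,domestic,neg_pos
Chongqing,2016-2020,domestic,pos_neg
Fujian,2016-2020,domestic,neg_pos
Gansu,2016-2020,domestic,neg_pos
Guangdong,2016-2020,domestic,neg_pos
Guangxi,2016-2020,domestic,pos_neg
Guizhou,2016-2020,domestic,neg_pos
Hainan,2016-2020,domestic,both_negative
Hebei,2016-2020,domestic,both_negative
Heilongjiang,2016-2020,domestic,neg_pos
Henan,2016-2020,domestic,pos_neg
Hubei,2016-2020,domestic,both_positive
Hunan,2016-2020,domestic,both_positive
Jiangsu,2016-2020,domestic,pos_neg
Jiangxi,2016-2020,domestic,both_negative
Jilin,2016-2020,domestic,both_negative
Liaoning,2016-2020,domestic,both_negative
Nei Mongol,2016-2020,domestic,both_positive
Ningxia,2016-2020,domestic,both_positive
Qinghai,2016-2020,domestic,both_positive
Shaanxi,2016-2020,domestic,both_positive
Shandong,2016-2020,domestic,neg_pos
Shanghai,2016-2020,domestic,both_negative
Shanxi,2016-2020,domestic,neg_pos
Sichuan,2016-2020,domestic,both_positive
Tianjin,2016-2020,domestic,both_positive
Xinjiang,2016-2020,domestic,pos_neg
Xizang,2016-2020,domestic,both_negative
Yunnan,2016-2020,domestic,both_negative
Zhejiang,2016-2020,domestic,neg_pos
Anhui,2011-2015,industrial,both_positive
Beijing,2011-2015,industrial,both_negative
Chongqing,2011-2015,industrial,both_positive
Fujian,2011-2015,industrial,both_positive
Gansu,2011-2015,industrial,both_positive
Guangdong,2011-2015,industrial,both_positive
Guangxi,2011-2015,industrial,neg_pos
Guizhou,2011-2015,industrial,both_positive
Hainan,2011-2015,industrial,both_negative
Hebei,2011-2015,industrial,both_positive
Heilongjiang,2011-2015,industrial,both_positive
Henan,2011-2015,industrial,both_positive
Hubei,2011-2015,industrial,both_positive
Hunan,2011-2015,industrial,pos_neg
Jiangsu,2011-2015,industrial,both_positive
Jiangxi,2011-2015,industrial,neg_pos
Jilin,2011-2015,industrial,neg_pos
Liaoning,2011-2015,industrial,both_negative
Nei Mongol,2011-2015,industrial,both_positive
Ningxia,2011-2015,industrial,both_positive
Qinghai,2011-2015,industrial,both_negative
Shaanxi,2011-2015,industrial,pos_neg
Shandong,2011-2015,industrial,both_negative
Shanghai,2011-2015,industrial,pos_neg
Shanxi,2011-2015,industrial,both_positive
Sichuan,2011-2015,industrial,neg_pos
Tianjin,2011-2015,industrial,both_positive
Xinjiang,2011-2015,industrial,neg_pos
Xizang,2011-2015,industrial,both_positive
Yunnan,2011-2015,industrial,pos_neg
Zhejiang,2011-2015,industrial,both_positive
Anhui,2016-2020,industrial,both_negative
Beijing,2016-2020,industrial,both_positive
Chongqing,2016-2020,industrial,both_positive
Fujian,2016-2020,industrial,both_positive
Gansu,2016-2020,industrial,neg_pos
Guangdong,2016-2020,industrial,both_positive
Guangxi,2016-2020,industrial,pos_neg
Guizhou,2016-2020,industrial,both_negative
Hainan,2016-2020,industrial,pos_neg
Hebei,2016-2020,industrial,both_positive
Heilongjiang,2016-2020,industrial,pos_neg
Henan,2016-2020,industrial,both_positive
Hubei,2016-2020,industrial,both_positive
Hunan,2016-2020,industrial,both_negative
Jiangsu,2016-2020,industrial,neg_pos
Jiangxi,2016-2020,industrial,both_positive
Jilin,2016-2020,industrial,both_positive
Liaoning,2016-2020,industrial,both_positive
Nei Mongol,2016-2020,industrial,both_negative
Ningxia,2016-2020,industrial,pos_neg
Qinghai,2016-2020,industrial,both_positive
Shaanxi,2016-2020,industrial,both_positive
Shandong,2016-2020,industrial,pos_neg
Shanghai,2016-2020,industrial,both_negative
Shanxi,2016-2020,industrial,both_negative
Sichuan,2016-2020,industrial,both_negative
Tianjin,2016-2020,industrial,neg_pos
Xinjiang,2016-2020,industrial,both_positive
Xizang,2016-2020,industrial,both_positive
Yunnan,2016-2020,industrial,both_negative
Zhejiang,2016-2020,industrial,neg_pos
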