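variable,unit,ls_value,ls_sd,now_value,now_sd,n
station_number,,323,,124,,
depth_m,m,794,,709,,
bottom_o2,ml l-1,4.1,,5.6,,
bottom_temperature,degC,1.2,,-0.1,,
bottom_salinity,,34.5,,34.4,,
sea_ice_cover_pct,%,0,,0,,
sediment_om_content_pct,%,11.3,,9.5,,
sediment_chl_a,mg DW m-2,12.9,,20.5,,
sediment_phaeopigments,mg DW m-2,64.5,,60.5,,
sediment_total_pigments,mg DW m-2,77.4,,81,,
chl_a_phaeopigment_ratio,,0.2,,0.34,,
cn_ratio,w/w,6.55,0.07,6.49,0.09,9
sediment_d13c,permil,-20.0,0.7,-20.6,0.7,3
sediment_d15n,permil,8.3,0.3,7.4,0.1,3
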